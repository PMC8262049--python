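# poresig

Nanopore raw-current (squiggle) comparison for epitranscriptomics: extract
per-5-mer signal instances from single-read Fast5 files, compare them with
penalized dynamic time warping, embed and summarize signal populations, and
statistically contrast modified (m6A, m5C) vs. unmodified base signals.

## Who this is for

Direct RNA nanopore sequencing records the ionic current while a strand
passes through the pore; base modifications perturb that current.  Anyone
trying to find signal features that discriminate a modified base from its
unmodified counterpart — as a precursor to building a classifier — needs
to pull out the current slice for each 5-mer occurrence, quantify how
similar those slices are, and inspect how modified and unmodified
populations separate.  `poresig` is the processing backend for exactly
that workflow, with deterministic CSV/TSV/JSON exports that any plotting
front end can consume, and a synthetic-read generator so the whole
pipeline is testable without sequencing data.

## The core algorithm

Signal instances for the same 5-mer vary in length (translocation speed
varies), so they are compared with dynamic time warping.  For current
series `A = a_1,…,a_n` and `B = b_1,…,b_m`, the distance is the minimum
over monotone, boundary-anchored warping paths `W`:

    DTW(A, B) = min_W  Σ_k d(w_k) + p · E(W)

where `d` is the local cost (squared difference by default, with the
accumulated total square-rooted), `E(W)` counts expansion/contraction
(non-diagonal) steps, and `p ≥ 0` is the **warping penalty**.  At `p = 0`
a short signal aligns almost freely to a long one at the same level; a
large penalty (e.g. `p = 100`) makes dwell-time differences expensive, so
classes that differ mainly in signal *length* — the signature of some
modifications — separate in the all-pairs distance matrix and its t-SNE
embedding.  Distance distributions within each 5-mer (box/violin
payloads), median/IQR averaged signals, and Welch's unequal-variance
t-test on signal lengths complete the picture.

## Worked example

Two populations of the 5-mer `GACCT` — "unmodified" (per-event dwell 10–20
samples) and "modified" (dwell 30–40), both at 100 pA with sd 5 — are
generated, tested for a length difference, and embedded at two penalties:

```python
import numpy as np
from poresig import similarity_matrix, tsne_embed, welch_t_test
from poresig.dtw import DTWParams
from poresig.simulate import make_two_class_benchmark

coll, labels = make_two_class_benchmark(n_per_class=100,
                                        contrast="length_shift", seed=0)
instances = list(coll.all_instances())
lengths = np.array([i.values.size for i in instances])
res = welch_t_test(lengths[labels == 0], lengths[labels == 1])
print(f"signal lengths: {res.mean_a:.1f} vs {res.mean_b:.1f} samples, "
      f"t = {res.t_statistic:.1f}, p = {res.p_value:.2e}")

from sklearn.cluster import KMeans
for penalty in (0.0, 100.0):
    m = similarity_matrix(instances, DTWParams(penalty=penalty))
    emb = tsne_embed(m, perplexity=30, seed=0)
    pred = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(emb.coords)
    purity = max((pred == labels).mean(), (pred != labels).mean())
    print(f"penalty {penalty:>5.0f}: 2-means purity on the embedding = {purity:.3f}")
```

prints

```
signal lengths: 14.9 vs 34.8 samples, t = -44.2, p = 1.53e-104
penalty     0: 2-means purity on the embedding = 0.885
penalty   100: 2-means purity on the embedding = 1.000
```

The length difference is overwhelmingly significant (Welch p ≈ 1e-104),
yet at penalty 0 the embedding mixes the classes noticeably; raising the
penalty to 100 makes dwell differences costly and the two classes separate
perfectly.  That penalty-0 → penalty-100 contrast is the central
diagnostic move this package supports.

## Command line

```sh
poresig simulate --out fixtures --n-reads 10 --n-sites 20 --seed 0
poresig extract fixtures/fast5 --min-instances 100 --sample-size 100 \
        --seed 0 --out-dir run
poresig dtw --instances run/instances.tsv --out run/matrix.tsv --penalty 100
poresig analyze --matrix run/matrix.tsv --instances run/instances.tsv \
        --out-dir run --perplexity 30 --seed 0
```

or `poresig all …` for the whole chain.  `extract` also accepts `--sam`
and `--sites` (BED3+ with id/base/strand columns) for modification-site-
centered extraction, and multiple Fast5 directories, which are tagged as
separate labels for two-dataset comparison.  Every stage logs its counts
to stderr and writes a JSON run manifest; identical seeds give
byte-identical outputs.

See `docs/methods.md` for the model, conventions and limitations.

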
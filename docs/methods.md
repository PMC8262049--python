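# Methods

## The signal model

An Oxford Nanopore sequencer records the ionic current through a pore while
a nucleic-acid strand translocates.  The pore senses roughly five
nucleotides at a time, so a basecalled read comes with an *events table*:
one row per 5-mer model state, annotated with the start index and sample
count of its slice of the raw current array.  Sliding the 5-mer window one
base at a time, every 5-mer occurrence owns a contiguous current slice —
its **signal instance**.  Instances of the same 5-mer pooled across reads
form that 5-mer's **cumulative signal**.

Two physical features carry most of the information that distinguishes a
modified base (m6A on adenosine, m5C on cytosine) from its unmodified
counterpart when it sits at the center of the sensed 5-mer:

1. **dwell time** — how long the 5-mer stays in the pore, i.e. the length
   of the signal instance, and
2. **current level** — the mean picoampere level while it is there.

Everything in this package is built to surface those two contrasts.

Stall rows (`move = 0`) in the events table represent the pore lingering on
the same 5-mer; their slices are concatenated into the single occurrence
they belong to.  Without this merge, one occurrence would be split into
duplicate fragments and per-5-mer counts would depend on pore kinetics
rather than sequence content.

## Penalized dynamic time warping

Signal instances have different lengths, so they are compared with dynamic
time warping.  For sequences `A = a_1..a_n` and `B = b_1..b_m`,

    DTW(A, B) = min over warping paths W of  Σ_k d(w_k) + p · E(W)

where the path moves monotonically from `(1,1)` to `(n,m)` with steps
diagonal/vertical/horizontal, `d` is the local cost, and `E(W)` counts the
non-diagonal steps (expansions/contractions).  The penalty `p ≥ 0` makes
length-compensating alignments expensive: at `p = 0` a short flat signal
aligns almost freely to a long flat one, while at `p = 100` every inserted
step costs, so instances that differ mainly in dwell time become distant.
That is precisely why a dwell-time contrast that is invisible in the
embedding at `p = 0` separates cleanly at `p = 100`.

Numerical conventions:

- default local cost is the squared difference with the accumulated total
  (penalty included) square-rooted at the end; an absolute-difference mode
  without the root is kept for hand-checkable arithmetic.  The square root
  commutes with the minimum, so the penalized recurrence remains an
  ordinary dynamic program;
- the penalty is charged exactly once per vertical or horizontal step,
  never on diagonal steps;
- an optional Sakoe–Chiba band limits `|i − j|`; the band is widened to the
  length difference when necessary so a path always exists;
- no z-normalization is applied before warping by default: the comparisons
  are between raw current levels, and normalizing away the level would
  erase one of the two contrasts of interest.

The similarity matrix computes the upper triangle only and mirrors it, so
symmetry and the zero diagonal hold exactly, entries are deterministic, and
run-to-run results are identical.  The DP kernel is JIT-compiled with
numba; a pure-Python fallback keeps the package importable without it.

Correctness of the kernel is established against an independent oracle:
exhaustive enumeration of every admissible warping path for short
sequences, which the DP must match to 1e-9 across penalties.

## Summaries, embedding, statistics

- **Within-5-mer distance distributions** (box/violin payloads) use
  linear-interpolation (type 7) quantiles everywhere, Tukey whiskers (most
  extreme points within 1.5 IQR of the quartiles), and a Gaussian KDE with
  Scott's bandwidth on 64 points for the violin outline — a rendering
  payload, not an inferential quantity.
- **Ranking** is alphabetical or by ascending median distance (most
  signal-uniform 5-mer first), ties broken lexicographically.
- **Wildcard filtering**: `*` matches exactly one of A/C/G/T; shorter
  patterns match as prefixes.
- **Length normalization** resamples a signal onto `L` equispaced points by
  linear interpolation; endpoints are preserved and the output range never
  leaves the input range.  Default `L` is the group's median original
  length — homogenize to a typical dwell rather than stretch everything to
  the longest signal.
- **Group averaging** computes the per-time-step median (the arithmetic
  mean is exposed as an option) with a 25th–75th percentile band.
- **Welch's t-test** on signal-length populations implements the t
  statistic and Welch–Satterthwaite degrees of freedom from the standard
  formulas (variances with the n−1 denominator); the two-sided p-value
  comes from Student's t distribution.  Two constant samples with equal
  means are rejected as degenerate; with different means the test reports
  t = ±∞, p = 0.
- **Embedding** uses t-SNE in precomputed-distance mode (scikit-learn) with
  random, seeded initialization — PCA initialization needs feature vectors,
  which distances are not.  Defaults: perplexity 30, learning rate 200,
  1000 iterations, seed 0; perplexity must lie in (1, n/3).  Fixed seed
  gives bit-identical coordinates.  Perplexity trades global for local
  structure: ~30 shows the large groups, ~7 resolves latent sub-shapes
  within a 5-mer.

## Site-centered extraction

Modification catalogs give reference coordinates.  A site's evidence in a
read is found by walking the alignment CIGAR to map the reference position
to a read position (None inside deletions/skips), then locating the merged
5-mer occurrence whose *center* (position 3 of 5) sits on that read
position.  Sites within 2 nt of a read end have no centered 5-mer and
yield None.  Reference coordinates are 0-based internally; BED input is
consumed as 0-based half-open and 1-based catalogs are accepted behind a
flag.  Only primary alignments are used, and — direct RNA being
single-stranded — a site is matched only to reads aligned on its strand;
minus-strand read positions are flipped from SAM's stored orientation back
to basecalled-read orientation before the events lookup.  Matched
unmodified controls are drawn uniformly (seeded) from region positions with
the same middle base, minus a known-modified exclusion set.

## The synthetic-data generator

The generator emulates exactly the features the pipeline measures:

- per-5-mer expected current levels from a seeded hash (range ±20 pA around
  the class mean) — identical 5-mers share a level, as with a pore-model
  table, without requiring one;
- per-event dwell drawn uniformly (or truncated-normally) from a class
  range; Gaussian sample noise; stalls injected with probability 0.05;
- two benchmark contrasts, 100 instances per class by default, mirroring
  the sample-100-signals-per-dataset workflow:
  - **length_shift** (dwell-time contrast): one shared 5-mer at 100 pA,
    sd 5, dwell 10–20 vs 30–40 samples per event;
  - **level_shift** (current-level contrast): same dwell 20–30, levels 80
    vs 100 pA, sd 5 — a 20 pA offset of the same magnitude as the average
    difference reported between m6A and unmodified A signal groups;
- a site fixture with a random reference, substring reads aligned with
  ungapped, deletion- and insertion-containing CIGARs in rotation, mappable
  sites centered on A/C bases, plus one site inside a deletion and one near
  a read edge whose correct extraction result is None.

What the generator does **not** emulate: sequence-context-dependent noise,
basecalling errors (events always match the true sequence), non-Gaussian
current distributions, signal drift within a read, and multi-isoform or
multi-mapping ambiguity.  Passing benchmarks therefore demonstrates that
the machinery measures what it claims under a known signal model — not
that real m6A/m5C calls at any particular accuracy follow.

## Problem sizes and determinism

The shipped benchmarks use 100 + 100 instances of one 5-mer (a 200×200 DTW
matrix, ~20k warping problems of length ≤ ~450 samples) — the same scale
as the interactive per-5-mer workflow the pipeline feeds.  All sampling,
simulation and embedding take explicit seeds; a dedicated
`numpy.random.Generator` is created per call and global random state is
never touched.  Reruns of the full CLI pipeline with the same seeds are
byte-identical.

## Known limitations

- Only the classic single-read Fast5 dialect (Albacore-style events table)
  is supported; multi-read Fast5, POD5 and VBZ-compressed files are
  refused with a clear error.  Event tables are consumed, never inferred:
  there is no re-segmentation of raw current.
- k is parameterized but only k = 5 is validated against the events table's
  model-state width; other k pass through with a warning.
- The n×n distance matrix is materialized densely; the intended scale is
  the few-hundred-instance per-5-mer workflow, not whole-run all-pairs
  analysis.
- The Welch comparison is a single test on one 5-mer's two groups; no
  multiple-testing correction across 5-mers is attempted or needed for it.
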
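"""Synthetic nanopore reads, alignments and site tables with known truth.

Every generator here is fully determined by its seed and records a manifest
of ground truth (per-kmer occurrence counts, per-event dwell and level,
site-to-instance mappings), so extraction, warping, embedding and site
mapping can all be tested offline against exact expectations.

The signal model is deliberately simple: each 5-mer has a class-dependent
expected current level (a seeded per-kmer lookup stands in for a pore-model
table, so identical 5-mers share a level), each event dwells a random
number of samples, and samples are the level plus Gaussian noise.  Stall
events (move = 0) are injected at a configurable rate to exercise the merge
rule.  The two benchmark generators emulate the two signal contrasts that
distinguish modified from unmodified bases in direct RNA data: a dwell-time
(signal length) shift, and a current-level shift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .extract import KmerCollection, SignalInstance
from .fast5 import EventRow, NanoporeRead, write_fast5

_BASES = "ACGT"

# benchmark study conditions: 100 signals per class, matching the
# sample-100-per-dataset workflow of the case studies
DEFAULT_N_PER_CLASS = 100
LENGTH_SHIFT_DWELLS = ((10, 20), (30, 40))
LEVEL_SHIFT_LEVELS = (80.0, 100.0)
BENCHMARK_LEVEL_SD = 5.0
BENCHMARK_LEVEL = 100.0
LEVEL_SHIFT_DWELL = (20, 30)


@dataclass(frozen=True)
class ClassSpec:
    """Signal-generation parameters for one read/instance class."""

    name: str
    level_mean: float = 100.0  # pA
    level_sd: float = 5.0
    dwell_min: int = 10
    dwell_max: int = 20
    length_distribution: str = "uniform"
    label: str = ""

    def __post_init__(self) -> None:
        if self.dwell_min < 1 or self.dwell_min > self.dwell_max:
            raise ValueError("need 1 <= dwell_min <= dwell_max")
        if self.level_sd < 0:
            raise ValueError("level_sd must be >= 0")
        if self.length_distribution not in ("uniform", "normal"):
            raise ValueError("length_distribution must be uniform or normal")


@dataclass
class FixtureManifest:
    """Ground truth sufficient to predict every downstream result exactly."""

    seed: int
    reads: list[dict] = field(default_factory=list)
    expected_kmer_counts: dict[str, int] = field(default_factory=dict)
    site_truth: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        return cls(**json.loads(Path(path).read_text()))


def kmer_level(kmer: str, seed: int, spread: float = 20.0) -> float:
    """Class-independent expected level offset for a 5-mer, from a seeded hash.

    Maps each 5-mer to a stable offset in [-spread, +spread] pA around the
    class mean.  A cryptographic hash keeps the lookup independent of the
    process hash seed.
    """
    digest = hashlib.sha256(f"{seed}:{kmer}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return (2.0 * u - 1.0) * spread


def _draw_dwell(spec: ClassSpec, rng: np.random.Generator) -> int:
    if spec.length_distribution == "uniform":
        return int(rng.integers(spec.dwell_min, spec.dwell_max + 1))
    mean = 0.5 * (spec.dwell_min + spec.dwell_max)
    sd = max(1e-9, (spec.dwell_max - spec.dwell_min) / 4.0)
    return int(np.clip(round(rng.normal(mean, sd)),
                       spec.dwell_min, spec.dwell_max))


def make_read(
    sequence: str,
    class_spec: ClassSpec,
    seed: int,
    read_id: str | None = None,
    stall_prob: float = 0.05,
) -> tuple[NanoporeRead, dict]:
    """Simulate one read: an event per 5-mer window plus its raw signal.

    Each of the len(sequence) - 4 windows gets one move=1 event; stall
    events (move=0, same 5-mer) follow with probability ``stall_prob``.
    The expected level of a window is the class mean plus the seeded
    per-5-mer offset; samples add Gaussian noise with the class sd.
    Fully reproducible from (sequence, spec, seed).
    """
    if len(sequence) < 5 or not set(sequence) <= set(_BASES):
        raise ValueError("sequence must be >= 5 bases over ACGT")
    rng = np.random.default_rng(seed)
    if read_id is None:
        read_id = f"sim_{seed}"

    events: list[EventRow] = []
    chunks: list[np.ndarray] = []
    dwells: list[int] = []
    means: list[float] = []
    kmer_counts: dict[str, int] = {}
    cursor = 0
    n_windows = len(sequence) - 4
    for w in range(n_windows):
        kmer = sequence[w : w + 5]
        kmer_counts[kmer] = kmer_counts.get(kmer, 0) + 1
        level = class_spec.level_mean + kmer_level(kmer, seed=0)
        n_rows = 1
        while stall_prob > 0 and rng.random() < stall_prob:
            n_rows += 1
        total_dwell = 0
        for row in range(n_rows):
            dwell = _draw_dwell(class_spec, rng)
            total_dwell += dwell
            events.append(
                EventRow(
                    model_state=kmer,
                    start=cursor,
                    length=dwell,
                    move=1 if row == 0 else 0,
                )
            )
            chunks.append(rng.normal(level, class_spec.level_sd, size=dwell))
            cursor += dwell
        dwells.append(total_dwell)
        means.append(level)

    read = NanoporeRead(
        read_id=read_id,
        signal=np.concatenate(chunks),
        events=events,
        metadata={"class": class_spec.name},
    )
    entry = {
        "read_id": read_id,
        "sequence": sequence,
        "class": class_spec.name,
        "label": class_spec.label,
        "dwells": dwells,
        "means": means,
        "kmer_counts": kmer_counts,
        "n_windows": n_windows,
    }
    return read, entry


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_two_class_benchmark(
    n_per_class: int = DEFAULT_N_PER_CLASS,
    contrast: str = "length_shift",
    seed: int = 0,
) -> tuple[KmerCollection, np.ndarray]:
    """Two labeled signal classes of one shared 5-mer.

    ``length_shift`` emulates a dwell-time contrast (same 100 pA level,
    sd 5; dwell uniform 10-20 vs 30-40 samples) as seen between m5C and
    unmodified C; ``level_shift`` emulates a current-level contrast
    (levels 80 vs 100 pA, sd 5, same dwell) as seen between m6A and
    unmodified A.  Returns the collection plus a 0/1 class-label vector
    aligned with the collection's instance order, for purity scoring.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if contrast == "length_shift":
        kmer = "GACCT"
        specs = [
            ClassSpec("unmodified", level_mean=BENCHMARK_LEVEL,
                      level_sd=BENCHMARK_LEVEL_SD,
                      dwell_min=LENGTH_SHIFT_DWELLS[0][0],
                      dwell_max=LENGTH_SHIFT_DWELLS[0][1], label="unmodified"),
            ClassSpec("modified", level_mean=BENCHMARK_LEVEL,
                      level_sd=BENCHMARK_LEVEL_SD,
                      dwell_min=LENGTH_SHIFT_DWELLS[1][0],
                      dwell_max=LENGTH_SHIFT_DWELLS[1][1], label="modified"),
        ]
    elif contrast == "level_shift":
        kmer = "ACAGT"
        specs = [
            ClassSpec("unmodified", level_mean=LEVEL_SHIFT_LEVELS[1],
                      level_sd=BENCHMARK_LEVEL_SD,
                      dwell_min=LEVEL_SHIFT_DWELL[0],
                      dwell_max=LEVEL_SHIFT_DWELL[1], label="unmodified"),
            ClassSpec("modified", level_mean=LEVEL_SHIFT_LEVELS[0],
                      level_sd=BENCHMARK_LEVEL_SD,
                      dwell_min=LEVEL_SHIFT_DWELL[0],
                      dwell_max=LEVEL_SHIFT_DWELL[1], label="modified"),
        ]
    else:
        raise ValueError("contrast must be 'length_shift' or 'level_shift'")

    rng = np.random.default_rng(seed)
    instances: list[SignalInstance] = []
    labels: list[int] = []
    for class_idx, spec in enumerate(specs):
        for i in range(n_per_class):
            dwell = _draw_dwell(spec, rng)
            values = rng.normal(spec.level_mean, spec.level_sd, size=dwell)
            instances.append(
                SignalInstance(
                    instance_id=f"{spec.label}:{kmer}:{i}",
                    kmer=kmer,
                    values=values,
                    read_id=f"{spec.label}_{i}",
                    event_index=0,
                    label=spec.label,
                )
            )
            labels.append(class_idx)
    coll = KmerCollection(
        instances={kmer: instances},
        provenance=f"two-class benchmark contrast={contrast} "
        f"n={n_per_class}/class seed={seed}",
    )
    return coll, np.array(labels)


def make_site_fixture(
    n_reads: int,
    n_sites: int,
    seed: int,
    out_dir: str | Path,
    read_span: int = 60,
    with_unmappable_sites: bool = True,
) -> tuple[Path, Path, Path, FixtureManifest]:
    """End-to-end site-extraction fixture: Fast5 dir, SAM, BED, manifest.

    Builds a random reference, aligns reads as exact substrings with
    ungapped, deletion-containing and insertion-containing CIGARs in
    rotation, places ``n_sites`` mappable sites centered on A or C bases,
    and (optionally) adds one site inside a deletion and one within 2 nt of
    a read end, whose expected extraction result is None.  The manifest
    records, for every site, the read and merged-occurrence index it must
    map to.
    """
    out_dir = Path(out_dir)
    fast5_dir = out_dir / "fast5"
    fast5_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref_name = "chrS"
    ref_len = max(400, read_span * (n_reads + 2))
    reference = random_sequence(ref_len, rng)
    manifest = FixtureManifest(seed=seed)
    spec = ClassSpec("fixture", level_mean=100.0, level_sd=5.0,
                     dwell_min=8, dwell_max=16)

    reads: list[tuple[str, str, int, list[tuple[str, int]]]] = []
    deletion_reads: list[int] = []
    for i in range(n_reads):
        ref_start = int(rng.integers(0, ref_len - read_span - 4))
        kind = ("match", "deletion", "insertion")[i % 3]
        if kind == "match":
            seq = reference[ref_start : ref_start + read_span]
            cigar = [("M", read_span)]
        elif kind == "deletion":
            half = read_span // 2
            seq = (reference[ref_start : ref_start + half]
                   + reference[ref_start + half + 2 : ref_start + read_span + 2])
            cigar = [("M", half), ("D", 2), ("M", read_span - half)]
            deletion_reads.append(i)
        else:
            half = read_span // 2
            insert = random_sequence(2, rng)
            seq = (reference[ref_start : ref_start + half] + insert
                   + reference[ref_start + half : ref_start + read_span])
            cigar = [("M", half), ("I", 2), ("M", read_span - half)]
        read_id = f"simread_{i:03d}"
        read, entry = make_read(seq, spec, seed=int(rng.integers(2**31)),
                                read_id=read_id, stall_prob=0.05)
        write_fast5(read, fast5_dir / f"{read_id}.fast5")
        entry["ref_start"] = ref_start
        entry["cigar"] = cigar
        manifest.reads.append(entry)
        for kmer, count in entry["kmer_counts"].items():
            manifest.expected_kmer_counts[kmer] = (
                manifest.expected_kmer_counts.get(kmer, 0) + count
            )
        reads.append((read_id, seq, ref_start, cigar))

    # mappable sites: center an A or C base away from read ends and gaps
    sites: list[tuple[str, int, str, str]] = []  # (site_id, ref_pos, base, strand)
    attempts = 0
    while len(sites) < n_sites and attempts < 10000:
        attempts += 1
        i = int(rng.integers(0, n_reads))
        read_id, seq, ref_start, cigar = reads[i]
        read_pos = int(rng.integers(2, len(seq) - 2))
        base = seq[read_pos]
        if base not in "AC":
            continue
        ref_pos = _read_to_ref(cigar, ref_start, read_pos)
        if ref_pos is None:
            continue  # inside an insertion: no reference coordinate
        site_id = f"site_{len(sites):03d}"
        sites.append((site_id, ref_pos, base, "+"))
        manifest.site_truth.append({
            "site_id": site_id,
            "read_id": read_id,
            "event_index": read_pos - 2,  # merged-occurrence (window) index
            "kmer": seq[read_pos - 2 : read_pos + 3],
            "label": "mappable",
        })
    if len(sites) < n_sites:
        raise ValueError(f"could only place {len(sites)} of {n_sites} sites")

    if with_unmappable_sites:
        if deletion_reads:
            i = deletion_reads[0]
            read_id, seq, ref_start, cigar = reads[i]
            del_ref_pos = ref_start + cigar[0][1]  # first deleted base
            base = reference[del_ref_pos]
            if base in "AC":
                sites.append(("site_del", del_ref_pos, base, "+"))
                manifest.site_truth.append({
                    "site_id": "site_del", "read_id": read_id,
                    "event_index": None, "kmer": None, "label": "in_deletion",
                })
        read_id, seq, ref_start, cigar = reads[0]
        for read_pos in range(2):
            if seq[read_pos] in "AC":
                ref_pos = _read_to_ref(cigar, ref_start, read_pos)
                sites.append(("site_edge", ref_pos, seq[read_pos], "+"))
                manifest.site_truth.append({
                    "site_id": "site_edge", "read_id": read_id,
                    "event_index": None, "kmer": None, "label": "near_edge",
                })
                break

    bed_path = out_dir / "sites.bed"
    with bed_path.open("w") as fh:
        for site_id, ref_pos, base, strand in sites:
            fh.write(f"{ref_name}\t{ref_pos}\t{ref_pos + 1}\t"
                     f"{site_id}\t{base}\t{strand}\n")

    sam_path = out_dir / "alignments.sam"
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for read_id, seq, ref_start, cigar in reads:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = read_id
            rec.query_sequence = seq
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = ref_start
            rec.mapping_quality = 60
            rec.cigartuples = [("MIDNSHP=X".index(op), n) for op, n in cigar]
            sam.write(rec)

    manifest.save(out_dir / "manifest.json")
    return fast5_dir, sam_path, bed_path, manifest


def _read_to_ref(cigar: list[tuple[str, int]], ref_start: int,
                 read_pos: int) -> int | None:
    """Inverse coordinate map for fixture construction (None in insertions)."""
    ref = ref_start
    read = 0
    for op, length in cigar:
        consumes_read = op in "MIS=X"
        consumes_ref = op in "MDN=X"
        if consumes_read and read <= read_pos < read + length:
            if not consumes_ref:
                return None
            return ref + (read_pos - read)
        if consumes_read:
            read += length
        if consumes_ref:
            ref += length
    return None
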
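"""Per-5-mer signal-instance extraction and pooling.

A nanopore senses five nucleotides at a time, so the basecaller annotates
each event with a 5-mer model state.  Sliding the window one nucleotide at
a time, every 5-mer occurrence in a read owns a contiguous slice of the raw
current trace — its *signal instance*.  Instances keep their native lengths
(dwell varies per occurrence); nothing is padded or truncated.

Consecutive events with ``move == 0`` are stalls: the pore lingered on the
same 5-mer, so their signal slices belong to one occurrence and are merged
into a single instance.  Repeated occurrences of the same 5-mer elsewhere in
a read stay separate — pooling those repetitions across reads is exactly
what the cumulative per-kmer collections are for.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ExtractionError, SamplingError
from .fast5 import NanoporeRead

log = logging.getLogger(__name__)


@dataclass
class SignalInstance:
    """One 5-mer occurrence's contiguous current slice."""

    instance_id: str
    kmer: str
    values: np.ndarray
    read_id: str
    event_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalInstance):
            return NotImplemented
        return (
            self.instance_id == other.instance_id
            and self.kmer == other.kmer
            and np.array_equal(self.values, other.values)
            and self.read_id == other.read_id
            and self.event_index == other.event_index
            and self.label == other.label
        )


@dataclass
class KmerCollection:
    """Signal instances grouped by 5-mer (the cumulative signals)."""

    instances: dict[str, list[SignalInstance]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for kmer, group in self.instances.items():
            for inst in group:
                if inst.kmer != kmer:
                    raise ValueError(
                        f"instance {inst.instance_id} has kmer {inst.kmer}, "
                        f"filed under {kmer}"
                    )
                if inst.instance_id in seen:
                    raise ValueError(f"duplicate instance_id {inst.instance_id}")
                seen.add(inst.instance_id)

    def kmers(self) -> list[str]:
        return list(self.instances.keys())

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.instances.items()}

    def total(self) -> int:
        return sum(len(v) for v in self.instances.values())

    def all_instances(self) -> Iterator[SignalInstance]:
        for group in self.instances.values():
            yield from group

    def by_id(self) -> dict[str, SignalInstance]:
        return {i.instance_id: i for i in self.all_instances()}


def extract_instances(read: NanoporeRead, k: int = 5) -> list[SignalInstance]:
    """Split a read's events table into per-5-mer signal instances.

    Returns one instance per 5-mer occurrence, in event order.  Stall rows
    (``move == 0``) are merged into the preceding occurrence: their signal
    slices concatenate, because the same 5-mer never left the pore.
    """
    if k != 5:
        warnings.warn(
            f"events carry 5-mer model states; k={k} is passed through "
            "without re-windowing",
            stacklevel=2,
        )
    instances: list[SignalInstance] = []
    current_slices: list[np.ndarray] = []
    current_kmer = ""
    current_event = -1

    def flush() -> None:
        if not current_slices:
            return
        ordinal = len(instances)
        instances.append(
            SignalInstance(
                instance_id=f"{read.read_id}:{ordinal}",
                kmer=current_kmer,
                values=np.concatenate(current_slices),
                read_id=read.read_id,
                event_index=current_event,
            )
        )

    for i, ev in enumerate(read.events):
        if ev.start + ev.length > read.signal.size:
            raise ExtractionError(
                f"event {i} of read {read.read_id} spans "
                f"[{ev.start}, {ev.start + ev.length}) beyond signal "
                f"({read.signal.size} samples)"
            )
        chunk = read.signal[ev.start : ev.start + ev.length]
        if ev.move == 0 and current_slices:
            current_slices.append(chunk)
        else:
            flush()
            current_slices = [chunk]
            current_kmer = ev.model_state
            current_event = i
    flush()
    return instances


def pool_instances(
    reads: Iterable[NanoporeRead], label: str | None = None
) -> KmerCollection:
    """Extract all reads and group the instances by 5-mer.

    The total instance count equals the sum of per-read counts; the label,
    when given, tags every instance (e.g. ``"modified"``).
    """
    grouped: dict[str, list[SignalInstance]] = {}
    n_reads = 0
    for read in reads:
        n_reads += 1
        for inst in extract_instances(read):
            if label is not None:
                inst = replace(inst, label=label)
            grouped.setdefault(inst.kmer, []).append(inst)
    return KmerCollection(
        instances=grouped,
        provenance=f"pooled from {n_reads} reads"
        + (f" (label={label})" if label else ""),
    )


def merge_collections(*colls: KmerCollection) -> KmerCollection:
    """Union of several collections (instance ids must stay unique)."""
    grouped: dict[str, list[SignalInstance]] = {}
    for coll in colls:
        for kmer, group in coll.instances.items():
            grouped.setdefault(kmer, []).extend(group)
    return KmerCollection(
        instances=grouped,
        provenance=" + ".join(c.provenance for c in colls if c.provenance),
    )


def filter_kmers(coll: KmerCollection, min_instances: int) -> KmerCollection:
    """Keep only 5-mers with at least ``min_instances`` occurrences.

    Case studies use ``min_instances = 100`` so that every surviving 5-mer
    supports a stable within-group distance distribution.
    """
    if min_instances < 1:
        raise ValueError("min_instances must be >= 1")
    kept = {
        kmer: group
        for kmer, group in coll.instances.items()
        if len(group) >= min_instances
    }
    return KmerCollection(
        instances=kept,
        provenance=f"{coll.provenance} | filtered min_instances={min_instances}",
    )


def sample_instances(
    coll: KmerCollection, n_per_kmer: int, seed: int
) -> KmerCollection:
    """Sample exactly ``n_per_kmer`` instances per 5-mer without replacement.

    Uses a dedicated generator seeded per call, so identical seeds give
    identical samples and global random state is never touched.  Order
    within each group is preserved from the input.
    """
    rng = np.random.default_rng(seed)
    sampled: dict[str, list[SignalInstance]] = {}
    for kmer in sorted(coll.instances):
        group = coll.instances[kmer]
        if len(group) < n_per_kmer:
            raise SamplingError(
                f"kmer {kmer} has {len(group)} instances, "
                f"cannot sample {n_per_kmer}"
            )
        idx = rng.choice(len(group), size=n_per_kmer, replace=False)
        sampled[kmer] = [group[i] for i in sorted(idx)]
    return KmerCollection(
        instances=sampled,
        provenance=f"{coll.provenance} | sampled {n_per_kmer}/kmer seed={seed}",
    )


# --- serialization -----------------------------------------------------------
#
# One TSV with columns instance_id, read_id, kmer, label and a JSON-array
# column of current values, plus an index JSON of per-kmer counts.  Floats
# use repr round-tripping, so write-then-read is bit-exact.

_COLUMNS = ("instance_id", "read_id", "kmer", "label", "values")


def write_collection(coll: KmerCollection, tsv_path: str | Path,
                     index_path: str | Path | None = None) -> None:
    tsv_path = Path(tsv_path)
    with tsv_path.open("w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for kmer in sorted(coll.instances):
            for inst in coll.instances[kmer]:
                values = json.dumps([float(v) for v in inst.values])
                fh.write(
                    f"{inst.instance_id}\t{inst.read_id}\t{inst.kmer}\t"
                    f"{inst.label if inst.label is not None else ''}\t{values}\n"
                )
    if index_path is not None:
        counts = {k: len(coll.instances[k]) for k in sorted(coll.instances)}
        Path(index_path).write_text(json.dumps(counts, indent=2) + "\n")


def read_collection(tsv_path: str | Path) -> KmerCollection:
    grouped: dict[str, list[SignalInstance]] = {}
    with Path(tsv_path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected collection header {header}")
        for line in fh:
            instance_id, read_id, kmer, label, values = line.rstrip("\n").split("\t")
            inst = SignalInstance(
                instance_id=instance_id,
                kmer=kmer,
                values=np.array(json.loads(values), dtype=np.float64),
                read_id=read_id,
                event_index=-1,
                label=label or None,
            )
            grouped.setdefault(kmer, []).append(inst)
    return KmerCollection(instances=grouped, provenance=str(tsv_path))
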
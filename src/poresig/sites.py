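"""Modification-site-centered signal extraction.

Catalogs of known RNA modification sites (m6A on adenosines, m5C on
cytosines) give reference coordinates.  To pull out the raw-current
evidence for one site, the reference position is mapped through the read's
SAM alignment into read coordinates by walking the CIGAR, the 5-mer
occurrence whose *center* base sits on that read position is located in the
events table, and that occurrence's signal instance is returned.  The same
machinery extracts matched unmodified controls: random reference positions
with the same middle base.

Conventions: reference coordinates are 0-based internally (BED input is
0-based half-open already; 1-based site lists are shifted on read).  Only
primary alignments are used.  Direct RNA reads are single-stranded, so a
site is matched only to reads aligned on the site's strand; for a
minus-strand alignment the CIGAR walk yields a position in the stored
(reverse-complemented) sequence, which is flipped back to basecalled-read
orientation before the events lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pysam

from .errors import IdentityError, RangeError, SamplingError
from .extract import SignalInstance, extract_instances
from .fast5 import NanoporeRead

_READ_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")
_CIGAR_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class ModificationSite:
    """One genomic modification site (or matched unmodified control)."""

    chrom: str
    position: int  # 0-based reference coordinate of the modified base
    strand: str
    base: str  # A for m6A-type sites, C for m5C-type
    site_id: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.base not in ("A", "C"):
            raise ValueError("base must be A (m6A-type) or C (m5C-type)")


@dataclass(frozen=True)
class ReadAlignment:
    """Primary alignment of one read, as parsed from SAM."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    cigar: tuple[tuple[str, int], ...]
    strand: str

    def __post_init__(self) -> None:
        for op, length in self.cigar:
            if op not in _CIGAR_OPS or length < 1:
                raise ValueError(f"bad CIGAR element ({op}, {length})")

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            n for op, n in self.cigar if op in _REF_CONSUMING
        )

    @property
    def read_length(self) -> int:
        """Length of the stored read sequence (soft clips included)."""
        return sum(n for op, n in self.cigar if op in _READ_CONSUMING)


def ref_to_read_pos(aln: ReadAlignment, ref_pos: int) -> int | None:
    """Map a reference coordinate to a 0-based stored-read position.

    Walks the CIGAR accumulating reference and read offsets.  Returns None
    when the position falls inside a deletion or reference skip (D/N).  For
    minus-strand alignments the returned position is in the stored
    (reverse-complemented) read, per SAM convention.
    """
    if not aln.ref_start <= ref_pos < aln.ref_end:
        raise RangeError(
            f"ref_pos {ref_pos} outside alignment span "
            f"[{aln.ref_start}, {aln.ref_end}) on {aln.ref_name}"
        )
    ref = aln.ref_start
    read = 0
    for op, length in aln.cigar:
        consumes_read = op in _READ_CONSUMING
        consumes_ref = op in _REF_CONSUMING
        if consumes_ref and ref <= ref_pos < ref + length:
            if not consumes_read:  # D or N: site deleted from the read
                return None
            return read + (ref_pos - ref)
        if consumes_ref:
            ref += length
        if consumes_read:
            read += length
    raise RangeError(f"ref_pos {ref_pos} not reached by CIGAR walk")


def site_kmer_signal(
    site: ModificationSite,
    aln: ReadAlignment,
    read: NanoporeRead,
    end_margin: int = 2,
) -> SignalInstance | None:
    """Signal instance of the 5-mer centered on a modification site.

    Returns None when the site is unaligned in this read (deletion), lies
    within ``end_margin`` nucleotides of a read end (no centered 5-mer
    exists), the read is on the other strand, or no event occurrence
    centers on it.  The returned instance carries the site id as its label.
    """
    if aln.read_id != read.read_id:
        raise IdentityError(
            f"alignment read_id {aln.read_id!r} != read {read.read_id!r}"
        )
    if aln.strand != site.strand:
        return None
    try:
        stored_pos = ref_to_read_pos(aln, site.position)
    except RangeError:
        return None
    if stored_pos is None:
        return None

    instances = extract_instances(read)
    read_len = len(instances) + 4  # one base per window plus the 5-mer tail
    if aln.strand == "-":
        # events are in basecalled-read orientation; SAM stores the revcomp
        pos = read_len - 1 - stored_pos
    else:
        pos = stored_pos
    if pos < end_margin or pos > read_len - 1 - end_margin:
        return None

    # window positions of the merged occurrences, from cumulative moves
    window_positions: list[int] = []
    pos_acc = 0
    for i, ev in enumerate(read.events):
        if i > 0:
            pos_acc += ev.move
        if i == 0 or ev.move > 0:
            window_positions.append(pos_acc)
    target_window = pos - 2  # site at center (position 3 of 5)
    try:
        idx = window_positions.index(target_window)
    except ValueError:
        return None
    inst = instances[idx]
    if inst.kmer[2] != site.base:
        return None
    return replace(inst, label=site.site_id)


def sample_control_sites(
    regions: list[tuple[str, int, int]],
    base: str,
    n: int,
    reference_getter: Callable[[str, int], str],
    seed: int,
    exclude: set[tuple[str, int]] | None = None,
    strand: str = "+",
) -> list[ModificationSite]:
    """Sample n unmodified control sites with the required middle base.

    Eligible positions are those inside the given 0-based half-open regions
    whose reference base matches ``base`` and which are not in the known-
    modified exclusion set.  Sampling is uniform without replacement from a
    generator seeded per call, so results are reproducible.
    """
    exclude = exclude or set()
    eligible: list[tuple[str, int]] = []
    for chrom, start, end in regions:
        for pos in range(start, end):
            if (chrom, pos) in exclude:
                continue
            if reference_getter(chrom, pos) == base:
                eligible.append((chrom, pos))
    if len(eligible) < n:
        raise SamplingError(
            f"only {len(eligible)} eligible positions for base {base}, "
            f"need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [
        ModificationSite(
            chrom=eligible[i][0],
            position=eligible[i][1],
            strand=strand,
            base=base,
            site_id=f"ctrl_{eligible[i][0]}_{eligible[i][1]}",
        )
        for i in idx
    ]


# --- SAM / BED input ---------------------------------------------------------

def load_alignments(sam_path: str | Path) -> dict[str, ReadAlignment]:
    """Primary alignments from a SAM file, keyed by read id."""
    alignments: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = tuple(
                (_CIGAR_OPS[op], length) for op, length in rec.cigartuples
            )
            alignments[rec.query_name] = ReadAlignment(
                read_id=rec.query_name,
                ref_name=rec.reference_name,
                ref_start=rec.reference_start,
                cigar=cigar,
                strand="-" if rec.is_reverse else "+",
            )
    return alignments


def read_sites(path: str | Path, one_based: bool = False
               ) -> list[ModificationSite]:
    """Site table as BED3+ (chrom, start, end, site_id, base, strand).

    BED starts are 0-based; pass ``one_based=True`` for 1-based catalogs.
    """
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start = fields[0], int(fields[1])
        site_id = fields[3] if len(fields) > 3 else f"{chrom}:{start}"
        base = fields[4] if len(fields) > 4 else "A"
        strand = fields[5] if len(fields) > 5 else "+"
        sites.append(
            ModificationSite(
                chrom=chrom,
                position=start - 1 if one_based else start,
                strand=strand,
                base=base,
                site_id=site_id,
            )
        )
    return sites


def extract_site_instances(
    sites: Iterable[ModificationSite],
    alignments: dict[str, ReadAlignment],
    reads: dict[str, NanoporeRead],
    label: str | None = None,
) -> list[SignalInstance]:
    """All (site, read) signal instances, one per covering primary alignment.

    ``label``, when given, overrides the per-site label so modified and
    control cohorts can be tagged as two datasets.
    """
    out: list[SignalInstance] = []
    for site in sites:
        for read_id, aln in alignments.items():
            if aln.ref_name != site.chrom:
                continue
            if not aln.ref_start <= site.position < aln.ref_end:
                continue
            read = reads.get(read_id)
            if read is None:
                continue
            inst = site_kmer_signal(site, aln, read)
            if inst is None:
                continue
            if label is not None:
                inst = replace(inst, label=label)
            out.append(
                replace(inst, instance_id=f"{site.site_id}:{inst.instance_id}")
            )
    return out
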
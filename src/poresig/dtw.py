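"""Penalized dynamic time warping and all-pairs similarity matrices.

Signal instances for the same 5-mer differ in length because translocation
speed varies, so they are compared with dynamic time warping: the minimum,
over monotone boundary-anchored warping paths, of the accumulated local
cost.  A warping *penalty* ``p`` is charged once per expansion or
contraction step — every vertical or horizontal move in the cost matrix —
and never on diagonal moves:

    DTW(A, B) = min over paths W of  sum_k d(w_k) + p * (# non-diagonal steps)

With the default squared local cost, ``d(a_i, b_j) = (a_i - b_j)^2`` and the
accumulated total (penalty included) is square-rooted at the end; with the
absolute cost, ``d = |a_i - b_j|`` and no root is taken.  Because the square
root is monotone, min-then-root equals root-then-min, so the penalized
recurrence stays a plain dynamic program.

A nonzero penalty makes length differences expensive: two flat signals at
the same level but different durations are nearly free to align at ``p = 0``
(the shorter one just expands), while at ``p = 100`` every expansion step
costs, which is what lets a downstream embedding separate signal classes
that differ mainly in dwell time.

The inner dynamic program is JIT-compiled with numba when available and
falls back to pure Python otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .extract import KmerCollection, SignalInstance

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(func):
            return func
        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass(frozen=True)
class DTWParams:
    """Warping parameters.

    penalty: cost added per expansion/contraction (non-diagonal) step; 0
        recovers classical DTW.
    window: optional Sakoe-Chiba band half-width restricting |i - j|; the
        band is widened to the length difference when necessary so a path
        always exists.  ``None`` means unconstrained.
    local_distance: "squared" (squared differences, total square-rooted) or
        "absolute" (absolute differences, no root).
    """

    penalty: float = 0.0
    window: int | None = None
    local_distance: str = "squared"

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.window is not None and self.window < 1:
            raise ValueError("window must be >= 1 when given")
        if self.local_distance not in ("squared", "absolute"):
            raise ValueError("local_distance must be 'squared' or 'absolute'")


@njit(cache=True)
def _dtw_accumulate(a, b, penalty, window, squared):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    inf = np.inf
    acc = np.full((n, m), inf)
    for i in range(n):
        lo = 0 if window < 0 else max(0, i - window)
        hi = m if window < 0 else min(m, i + window + 1)
        for j in range(lo, hi):
            diff = a[i] - b[j]
            d = diff * diff if squared else abs(diff)
            if i == 0 and j == 0:
                acc[i, j] = d
                continue
            best = inf
            if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            if i > 0 and acc[i - 1, j] + penalty < best:
                best = acc[i - 1, j] + penalty
            if j > 0 and acc[i, j - 1] + penalty < best:
                best = acc[i, j - 1] + penalty
            acc[i, j] = d + best
    return acc[n - 1, m - 1]


def dtw_distance(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    params: DTWParams = DTWParams(),
) -> float:
    """Penalized DTW distance between two signals (symmetric in a, b)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("sequences must not contain NaN")
    if params.window is None:
        window = -1
    else:
        # a band narrower than the length difference admits no path
        window = max(params.window, abs(a.size - b.size))
    total = _dtw_accumulate(
        a, b, float(params.penalty), window, params.local_distance == "squared"
    )
    if params.local_distance == "squared":
        return float(np.sqrt(total))
    return float(total)


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs DTW distance matrix over signal instances."""

    ids: list[str]
    values: np.ndarray
    params: DTWParams = field(default_factory=DTWParams)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.isfinite(v).all():
            raise ValueError("matrix contains non-finite entries")
        if (v < 0).any():
            raise ValueError("matrix contains negative distances")
        if np.diagonal(v).any():
            raise ValueError("matrix diagonal must be zero")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


def similarity_matrix(
    source: KmerCollection | Sequence[SignalInstance],
    params: DTWParams = DTWParams(),
) -> SimilarityMatrix:
    """All-pairs penalized-DTW matrix, zero diagonal, exact mirror symmetry.

    Only the upper triangle is computed; each entry is mirrored, so the
    matrix is symmetric by construction and the result is deterministic.
    """
    if isinstance(source, KmerCollection):
        instances = list(source.all_instances())
    else:
        instances = list(source)
    if len(instances) < 2:
        raise ValueError("similarity matrix needs at least 2 instances")
    n = len(instances)
    values = np.zeros((n, n), dtype=np.float64)
    signals = [inst.values for inst in instances]
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(signals[i], signals[j], params)
            values[i, j] = d
            values[j, i] = d
    return SimilarityMatrix(
        ids=[inst.instance_id for inst in instances], values=values,
        params=params,
    )


def within_kmer_distances(
    matrix: SimilarityMatrix, coll: KmerCollection
) -> dict[str, list[float]]:
    """Upper-triangle distances among each 5-mer's own instances.

    A 5-mer with n instances in the matrix contributes n(n-1)/2 distances;
    5-mers with fewer than 2 instances are omitted with a logged warning.
    These per-kmer multisets are the box/violin payloads: the tighter the
    distribution sits near zero, the more uniform that 5-mer's signals.
    """
    pos = {iid: k for k, iid in enumerate(matrix.ids)}
    missing = [i.instance_id for i in coll.all_instances()
               if i.instance_id not in pos]
    if missing:
        raise ValueError(
            f"{len(missing)} collection instances absent from matrix ids "
            f"(first: {missing[0]})"
        )
    out: dict[str, list[float]] = {}
    for kmer in sorted(coll.instances):
        idx = [pos[i.instance_id] for i in coll.instances[kmer]]
        if len(idx) < 2:
            log.warning("kmer %s has < 2 instances; omitted", kmer)
            continue
        dists = [
            float(matrix.values[idx[i], idx[j]])
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
        ]
        out[kmer] = dists
    return out


# --- serialization -----------------------------------------------------------

def write_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """TSV with instance ids as header row/column and params in a comment."""
    path = Path(path)
    meta = {
        "penalty": matrix.params.penalty,
        "window": matrix.params.window,
        "local_distance": matrix.params.local_distance,
    }
    with path.open("w") as fh:
        fh.write(f"# params={json.dumps(meta)}\n")
        fh.write("\t".join(["id", *matrix.ids]) + "\n")
        for iid, row in zip(matrix.ids, matrix.values):
            fh.write(iid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# params="):
            raise ValueError(f"{path} is not a similarity-matrix TSV")
        meta = json.loads(first[len("# params="):])
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[1:]
        rows = []
        row_ids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_ids != ids:
        raise ValueError("matrix row ids do not match column ids")
    return SimilarityMatrix(
        ids=ids,
        values=np.array(rows, dtype=np.float64),
        params=DTWParams(
            penalty=meta["penalty"],
            window=meta["window"],
            local_distance=meta["local_distance"],
        ),
    )
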
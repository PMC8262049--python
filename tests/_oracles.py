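"""Independent reference implementations used only as test oracles.

Each function here recomputes a quantity by the most transparent route
available — exhaustive enumeration, sorting, or the textbook formula —
deliberately sharing no code with the implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def dtw_brute_force(a, b, penalty: float, squared: bool = True) -> float:
    """Minimum warp cost by exhaustive enumeration of all monotone paths.

    Steps are diagonal/vertical/horizontal, anchored at both ends; each
    non-diagonal step adds ``penalty``.  Exponential, so only for tiny
    sequences.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    best = math.inf

    stack = [(0, 0, 0.0)]
    while stack:
        i, j, cost = stack.pop()
        d = (a[i] - b[j]) ** 2 if squared else abs(a[i] - b[j])
        cost += d
        if cost >= best:
            continue
        if i == n - 1 and j == m - 1:
            best = cost
            continue
        if i + 1 < n and j + 1 < m:
            stack.append((i + 1, j + 1, cost))
        if i + 1 < n:
            stack.append((i + 1, j, cost + penalty))
        if j + 1 < m:
            stack.append((i, j + 1, cost + penalty))
    return math.sqrt(best) if squared else best


def quantile_type7(data, q: float) -> float:
    """Linear-interpolation (type 7) quantile from an explicit sort."""
    xs = sorted(float(x) for x in data)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def welch_reference(a, b) -> tuple[float, float, float]:
    """Welch t, df and two-sided p from the textbook formulas (via mpmath-free
    scipy CDF only for the final tail probability)."""
    from scipy.stats import t as t_dist

    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2a, se2b = va / na, vb / nb
    t = (ma - mb) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (na - 1) + se2b**2 / (nb - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, df, p


def expand_cigar_pairs(cigar, ref_start: int):
    """Per-base (read_pos, ref_pos) pairs from a CIGAR, None in gaps.

    Returns a dict ref_pos -> read_pos (or None for D/N), covering the
    reference span of the alignment.
    """
    mapping: dict[int, int | None] = {}
    ref = ref_start
    read = 0
    for op, length in cigar:
        if op in "M=X":
            for k in range(length):
                mapping[ref + k] = read + k
            ref += length
            read += length
        elif op in "IS":
            read += length
        elif op in "DN":
            for k in range(length):
                mapping[ref + k] = None
            ref += length
        # H, P consume nothing relevant
    return mapping


def kmeans_purity(coords, labels, seed: int = 0) -> float:
    """Best label agreement of 2-means clusters on 2-D coordinates."""
    from sklearn.cluster import KMeans

    pred = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(coords)
    labels = np.asarray(labels)
    return float(max((pred == labels).mean(), (pred != labels).mean()))
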
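"""Per-5-mer distribution summaries, signal averaging, and Welch's t-test.

These are the computed payloads behind the usual squiggle-browser views:
box/violin statistics of within-5-mer DTW distances, wildcard filtering and
ranking of the 5-mer list, length normalization of variable-dwell signals,
group averages with interquartile bands, and the unequal-variance t-test
used to compare signal-length populations between a modified and an
unmodified dataset.

Quantiles use linear interpolation (type 7) throughout; the Welch statistic
and Welch-Satterthwaite degrees of freedom are computed from the standard
formulas directly, with the two-sided p-value taken from Student's t.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, PatternError
from .extract import SignalInstance

_PATTERN_CHARS = frozenset("ACGT*")


@dataclass(frozen=True)
class KmerSummary:
    """Box/violin payload for one 5-mer's within-group distance distribution."""

    kmer: str
    n_instances: int
    n_pairs: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    kde_points: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if self.n_pairs != self.n_instances * (self.n_instances - 1) // 2:
            raise ValueError("n_pairs inconsistent with n_instances")


@dataclass(frozen=True)
class AveragedSignal:
    """Length-normalized group average with a 25th-75th percentile band."""

    kmer: str
    length: int
    center: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_signals: int

    def __post_init__(self) -> None:
        for name in ("center", "band_low", "band_high"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.float64))
        if not (len(self.center) == len(self.band_low)
                == len(self.band_high) == self.length):
            raise ValueError("series lengths disagree with declared length")
        if ((self.band_low > self.center) | (self.center > self.band_high)).any():
            raise ValueError("band does not bracket center")


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance two-sample t-test result."""

    t_statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def summarize_kmer(distances: list[float] | np.ndarray, kmer: str,
                   n_instances: int | None = None) -> KmerSummary:
    """Summarize a 5-mer's within-group distance multiset.

    Quartiles are linear-interpolation quantiles; whiskers follow the Tukey
    convention (most extreme observations within 1.5 IQR of the quartiles);
    ``kde_points`` is a Gaussian KDE with Scott's bandwidth evaluated on 64
    equispaced points over [min, max], or None when the data are degenerate
    (fewer than 2 distinct values).

    ``n_instances`` is the size of the instance group the distances came
    from; when omitted it is inferred from the pair count n(n-1)/2.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one distance")
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())

    if n_instances is None:
        # invert n(n-1)/2 = n_pairs
        n_instances = int(round((1 + np.sqrt(1 + 8 * d.size)) / 2))

    kde_points = None
    if np.unique(d).size >= 2:
        kde = stats.gaussian_kde(d, bw_method="scott")
        xs = np.linspace(d.min(), d.max(), 64)
        kde_points = [(float(x), float(y)) for x, y in zip(xs, kde(xs))]

    return KmerSummary(
        kmer=kmer,
        n_instances=n_instances,
        n_pairs=n_instances * (n_instances - 1) // 2,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        kde_points=kde_points,
    )


def rank_kmers(summaries: list[KmerSummary], mode: str = "median"
               ) -> list[KmerSummary]:
    """Order the 5-mer list alphabetically or by ascending median distance.

    Median ordering puts the most signal-uniform 5-mers first; ties break
    lexicographically.
    """
    if mode == "alphabetical":
        return sorted(summaries, key=lambda s: s.kmer)
    if mode == "median":
        return sorted(summaries, key=lambda s: (s.median, s.kmer))
    raise ValueError(f"unknown ranking mode {mode!r}")


def match_kmers(kmers: list[str], pattern: str) -> list[str]:
    """Filter a 5-mer list by a prefix pattern with ``*`` wildcards.

    ``*`` matches exactly one of A/C/G/T; a pattern shorter than 5 matches
    as a prefix (so ``"GAC"`` selects the 16 5-mers with that prefix, and
    ``"AACA*"`` selects AACAA, AACAC, AACAG, AACAT).  Input order is kept.
    """
    if len(pattern) > 5 or not set(pattern) <= _PATTERN_CHARS:
        raise PatternError(
            f"pattern {pattern!r} must be <= 5 characters over A,C,G,T,*"
        )
    regex = re.compile("".join("[ACGT]" if c == "*" else c for c in pattern))
    return [k for k in kmers if regex.match(k)]


def normalize_length(values: list[float] | np.ndarray, L: int) -> np.ndarray:
    """Resample a signal to L points by linear interpolation.

    Endpoints are preserved exactly and the output range stays within the
    input range, so normalization homogenizes duration without inventing
    current levels.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 1:
        raise ValueError("need at least one value")
    if L < 2:
        raise ValueError("L must be >= 2")
    if v.size == 1:
        return np.full(L, v[0])
    old_x = np.arange(v.size, dtype=np.float64)
    new_x = np.linspace(0.0, v.size - 1.0, L)
    return np.interp(new_x, old_x, v)


def average_group(instances: list[SignalInstance], L: int | None = None,
                  center: str = "median") -> AveragedSignal:
    """Average a group of same-5-mer signals after length normalization.

    Each instance is resampled to L points (default: the group's median
    original length), then per-time-step center (median by default, mean
    optional) and 25th/75th percentile band are computed.
    """
    if not instances:
        raise ValueError("need at least one instance")
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    if L is None:
        L = max(2, int(round(float(np.median([i.values.size
                                              for i in instances])))))
    stack = np.vstack([normalize_length(i.values, L) for i in instances])
    center_series = (np.median(stack, axis=0) if center == "median"
                     else stack.mean(axis=0))
    band_low = np.quantile(stack, 0.25, axis=0)
    band_high = np.quantile(stack, 0.75, axis=0)
    if center == "mean":
        # the mean can leave the IQR band; clip the band onto it
        band_low = np.minimum(band_low, center_series)
        band_high = np.maximum(band_high, center_series)
    kmers = {i.kmer for i in instances}
    kmer = kmers.pop() if len(kmers) == 1 else "mixed"
    return AveragedSignal(
        kmer=kmer,
        length=L,
        center=center_series,
        band_low=band_low,
        band_high=band_high,
        n_signals=len(instances),
    )


def write_summaries_tsv(summaries: list[KmerSummary], path) -> None:
    """One row per 5-mer: counts, quartiles and whiskers."""
    from pathlib import Path

    cols = ("kmer", "n_instances", "n_pairs", "median", "q1", "q3",
            "whisker_low", "whisker_high")
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fh.write(
                f"{s.kmer}\t{s.n_instances}\t{s.n_pairs}\t{s.median!r}\t"
                f"{s.q1!r}\t{s.q3!r}\t{s.whisker_low!r}\t{s.whisker_high!r}\n"
            )


def summaries_payload(summaries: list[KmerSummary]) -> dict:
    """JSON-ready box/violin payload (quartiles, whiskers, KDE points)."""
    return {
        "kmers": [
            {
                "kmer": s.kmer,
                "n_instances": s.n_instances,
                "n_pairs": s.n_pairs,
                "box": {
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                },
                "violin": (
                    [{"distance": x, "density": y} for x, y in s.kde_points]
                    if s.kde_points is not None
                    else None
                ),
            }
            for s in summaries
        ]
    }


def write_averaged_tsv(averages: list[AveragedSignal], path) -> None:
    """Long-format TSV: kmer, t, center, band_low, band_high."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("kmer\tt\tcenter\tband_low\tband_high\n")
        for avg in averages:
            for t in range(avg.length):
                fh.write(
                    f"{avg.kmer}\t{t}\t{avg.center[t]!r}\t"
                    f"{avg.band_low[t]!r}\t{avg.band_high[t]!r}\n"
                )


def welch_t_test(lengths_a, lengths_b) -> WelchResult:
    """Welch's unequal-variance t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch-Satterthwaite degrees of freedom; variances use the n-1
    denominator.  Used to compare signal-length populations between a
    modified and an unmodified group.
    """
    a = np.asarray(lengths_a, dtype=np.float64)
    b = np.asarray(lengths_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise DegenerateInputError(
                "both samples are constant with equal means; t is undefined"
            )
        # constant samples with different means: infinitely significant
        return WelchResult(
            t_statistic=float(np.inf) if a.mean() > b.mean() else float(-np.inf),
            df=float(a.size + b.size - 2),
            p_value=0.0,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            n_a=int(a.size), n_b=int(b.size),
        )
    sa = va / a.size
    sb = vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(
        t_statistic=float(t),
        df=float(df),
        p_value=float(min(1.0, p)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )
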
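"""2-D embedding of signal instances from a precomputed DTW matrix.

t-SNE consumes the all-pairs penalized-DTW matrix directly as precomputed
distances — signals are never re-featurized — and maps each instance to a
point in the plane so that similar signals land close together.  Perplexity
controls the effective neighborhood size: high values show the large-scale
group structure, low values break groups into local sub-shapes.  The
embedding is seeded and deterministic, and rectangular selections can be
exported with their raw current values for downstream inspection.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.manifold import TSNE

from .dtw import SimilarityMatrix
from .errors import ParameterError
from .extract import KmerCollection

DEFAULT_PERPLEXITY = 30.0
DEFAULT_LEARNING_RATE = 200.0
DEFAULT_N_ITER = 1000

# the browser workflow overlays up to four 5-mers at once; more is allowed
# but large matrices get slow, so warn rather than refuse
SOFT_MAX_KMERS = 4


@dataclass
class Embedding2D:
    """Per-instance 2-D coordinates plus the parameters that produced them."""

    ids: list[str]
    coords: np.ndarray
    perplexity: float
    learning_rate: float
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be n x 2 matching ids")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")


def tsne_embed(
    matrix: SimilarityMatrix,
    perplexity: float = DEFAULT_PERPLEXITY,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> Embedding2D:
    """Embed a similarity matrix into 2-D with seeded t-SNE.

    The matrix is treated as precomputed distances with random (seeded)
    initialization — PCA initialization would need feature vectors, which
    distances are not.  Identical inputs and seed give identical
    coordinates.
    """
    n = matrix.n
    if n < 4:
        raise ValueError("need at least 4 instances to embed")
    if not 1.0 < perplexity < n / 3.0:
        raise ParameterError(
            f"perplexity must lie in (1, n/3) = (1, {n / 3:.1f}); "
            f"got {perplexity}"
        )
    matrix.validate()
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=max(250, n_iter),
        metric="precomputed",
        init="random",
        random_state=seed,
    )
    coords = tsne.fit_transform(matrix.values)
    return Embedding2D(
        ids=list(matrix.ids),
        coords=np.asarray(coords, dtype=np.float64),
        perplexity=perplexity,
        learning_rate=learning_rate,
        n_iter=n_iter,
        seed=seed,
    )


def select_points(
    emb: Embedding2D, rect: tuple[float, float, float, float]
) -> list[str]:
    """Instance ids inside a closed rectangle (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = rect
    if xmin > xmax or ymin > ymax:
        raise ValueError("rectangle must satisfy xmin <= xmax and ymin <= ymax")
    x, y = emb.coords[:, 0], emb.coords[:, 1]
    inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    return [iid for iid, hit in zip(emb.ids, inside) if hit]


def export_selection(
    coll: KmerCollection, ids: list[str], path: str | Path
) -> None:
    """CSV of selected instances with their raw current values.

    One row per instance: instance_id, kmer, label, then the current values.
    Values are written with full repr precision, so re-parsing recovers them
    bit-for-bit.
    """
    by_id = coll.by_id()
    for iid in ids:
        if iid not in by_id:
            raise KeyError(f"unknown instance id {iid!r}")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["instance_id", "kmer", "label", "values"])
        for iid in ids:
            inst = by_id[iid]
            writer.writerow([
                inst.instance_id,
                inst.kmer,
                inst.label if inst.label is not None else "",
                json.dumps([float(v) for v in inst.values]),
            ])


def write_embedding_csv(
    emb: Embedding2D, coll: KmerCollection | None, path: str | Path
) -> None:
    """CSV of embedding coordinates (instance_id, kmer, label, x, y)."""
    by_id = coll.by_id() if coll is not None else {}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["instance_id", "kmer", "label", "x", "y"])
        for iid, (x, y) in zip(emb.ids, emb.coords):
            inst = by_id.get(iid)
            writer.writerow([
                iid,
                inst.kmer if inst else "",
                (inst.label or "") if inst else "",
                repr(float(x)),
                repr(float(y)),
            ])


def write_embedding_json(
    emb: Embedding2D, coll: KmerCollection | None, path: str | Path
) -> None:
    """JSON payload (coords, kmer color keys, params) for an external viewer."""
    by_id = coll.by_id() if coll is not None else {}
    kmers = sorted({i.kmer for i in by_id.values()}) if by_id else []
    payload = {
        "params": {
            "perplexity": emb.perplexity,
            "learning_rate": emb.learning_rate,
            "n_iter": emb.n_iter,
            "seed": emb.seed,
        },
        "kmers": kmers,
        "points": [
            {
                "instance_id": iid,
                "kmer": by_id[iid].kmer if iid in by_id else None,
                "label": by_id[iid].label if iid in by_id else None,
                "x": float(x),
                "y": float(y),
            }
            for iid, (x, y) in zip(emb.ids, emb.coords)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
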
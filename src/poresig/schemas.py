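"""Pydantic schemas for the machine-readable JSON payloads.

The pipeline's exports are meant to be consumed by an external viewer, so
their shapes are pinned down here and every payload the CLI writes is
validated against these models before it hits disk.
"""

from __future__ import annotations

from pydantic import BaseModel


class BoxStats(BaseModel):
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


class ViolinPoint(BaseModel):
    distance: float
    density: float


class KmerEntry(BaseModel):
    kmer: str
    n_instances: int
    n_pairs: int
    box: BoxStats
    violin: list[ViolinPoint] | None


class SummariesPayload(BaseModel):
    kmers: list[KmerEntry]


class EmbeddingParams(BaseModel):
    perplexity: float
    learning_rate: float
    n_iter: int
    seed: int


class EmbeddingPoint(BaseModel):
    instance_id: str
    kmer: str | None
    label: str | None
    x: float
    y: float


class EmbeddingPayload(BaseModel):
    params: EmbeddingParams
    kmers: list[str]
    points: list[EmbeddingPoint]


class WelchReport(BaseModel):
    label_a: str
    label_b: str
    quantity: str
    t_statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


class StageCounts(BaseModel):
    total: int
    filtered: int
    sampled: int


class RunManifest(BaseModel):
    command: str
    seed: int
    params: dict[str, float | int | str | None]
    counts: StageCounts | None = None
    outputs: list[str]
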
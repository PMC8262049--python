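"""Single-read Fast5 (HDF5) input/output.

The supported dialect is the classic one-read-per-file layout written by the
early basecallers: a raw current trace under ``/Raw/Reads/Read_<n>/Signal``
and a basecalled events table under
``/Analyses/Basecall_1D_000/BaseCalled_template/Events`` whose rows carry a
5-mer model state plus start/length indices into the signal array.  Signal
indices are 0-based and half-open: an event with ``start`` and ``length``
owns ``signal[start : start + length]``.

Raw DAC values are converted to picoamperes when the standard channel
calibration attributes (``digitisation``, ``offset``, ``range``) are present
under ``/UniqueGlobalKey/channel_id``; otherwise values pass through
unchanged with a logged warning.  Downstream analyses compare signals to
each other, so they are invariant to this affine convention.

Multi-read Fast5, bulk Fast5 and POD5 are out of scope; the reader detects
the multi-read layout and refuses it with a clear error instead of
misparsing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import DuplicateReadError, FormatError

log = logging.getLogger(__name__)

_SIGNAL_GROUP = "Raw/Reads"
_EVENTS_PATH = "Analyses/Basecall_1D_000/BaseCalled_template/Events"
_CHANNEL_PATH = "UniqueGlobalKey/channel_id"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class EventRow:
    """One row of a basecalled events table.

    ``model_state`` is the 5-mer occupying the pore, ``start``/``length``
    delimit its raw-signal slice (0-based, half-open) and ``move`` counts how
    many new nucleotides entered the pore relative to the previous event
    (0 = stall on the same 5-mer).
    """

    model_state: str
    start: int
    length: int
    move: int

    def validate(self, k: int = 5) -> None:
        if len(self.model_state) != k or not set(self.model_state) <= _BASES:
            raise FormatError(
                f"model_state {self.model_state!r} is not a {k}-mer over ACGT"
            )
        if self.start < 0 or self.length <= 0 or self.move < 0:
            raise FormatError(
                f"invalid event geometry start={self.start} "
                f"length={self.length} move={self.move}"
            )


@dataclass
class NanoporeRead:
    """One read: raw current trace plus its ordered events table.

    ``signal`` holds current values (picoamperes once calibrated).
    ``metadata`` is a free-form string map (sampling rate, channel, ...).
    """

    read_id: str
    signal: np.ndarray
    events: list[EventRow]
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.events and self.signal.size == 0:
            raise FormatError("no signal")
        if not self.events:
            raise FormatError("no events")
        prev: EventRow | None = None
        for i, ev in enumerate(self.events):
            ev.validate()
            if ev.start + ev.length > self.signal.size:
                raise FormatError(
                    f"event range invalid: event {i} spans "
                    f"[{ev.start}, {ev.start + ev.length}) but signal has "
                    f"{self.signal.size} samples"
                )
            if prev is not None:
                if ev.start < prev.start:
                    raise FormatError(f"events out of order at row {i}")
                if ev.move == 0 and ev.model_state != prev.model_state:
                    raise FormatError(
                        f"stall event {i} changes model_state "
                        f"({prev.model_state} -> {ev.model_state})"
                    )
            prev = ev

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NanoporeRead):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and np.array_equal(self.signal, other.signal)
            and self.events == other.events
            and self.metadata == other.metadata
        )


def _looks_multi_read(h5: h5py.File) -> bool:
    return any(key.startswith("read_") for key in h5.keys())


def read_fast5(path: str | Path) -> NanoporeRead:
    """Parse a single-read Fast5 file into a :class:`NanoporeRead`.

    Raises :class:`FormatError` when the signal dataset or events table is
    missing, when an event points outside the signal array, or when the file
    uses the unsupported multi-read layout.
    """
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if _looks_multi_read(h5):
            raise FormatError(f"multi-read Fast5 unsupported: {path}")
        if _SIGNAL_GROUP not in h5:
            raise FormatError(f"no signal in {path}")
        reads_group = h5[_SIGNAL_GROUP]
        read_names = sorted(reads_group.keys())
        if not read_names:
            raise FormatError(f"no signal in {path}")
        read_group = reads_group[read_names[0]]
        if "Signal" not in read_group:
            raise FormatError(f"no signal in {path}")
        raw = np.asarray(read_group["Signal"][()], dtype=np.float64)

        read_id = read_group.attrs.get("read_id", path.stem)
        if isinstance(read_id, bytes):
            read_id = read_id.decode()

        signal = _calibrate(h5, raw, path)

        if _EVENTS_PATH not in h5:
            raise FormatError(f"no events in {path}")
        table = h5[_EVENTS_PATH][()]
        if table.size == 0:
            raise FormatError(f"no events in {path}")
        events = []
        for row in table:
            state = row["model_state"]
            if isinstance(state, bytes):
                state = state.decode()
            events.append(
                EventRow(
                    model_state=state,
                    start=int(row["start"]),
                    length=int(row["length"]),
                    move=int(row["move"]),
                )
            )

        metadata = {
            str(k): str(v) for k, v in read_group.attrs.items() if k != "read_id"
        }

    read = NanoporeRead(read_id=str(read_id), signal=signal, events=events,
                        metadata=metadata)
    read.validate()
    return read


def _calibrate(h5: h5py.File, raw: np.ndarray, path: Path) -> np.ndarray:
    """DAC -> pA using channel attributes; pass-through when absent."""
    if _CHANNEL_PATH in h5:
        attrs = h5[_CHANNEL_PATH].attrs
        if all(a in attrs for a in ("digitisation", "offset", "range")):
            scale = float(attrs["range"]) / float(attrs["digitisation"])
            return (raw + float(attrs["offset"])) * scale
    log.warning("no channel calibration in %s; signal passed through as-is", path)
    return raw


def write_fast5(read: NanoporeRead, path: str | Path) -> None:
    """Write a read in the dialect :func:`read_fast5` consumes.

    The signal is stored as float64 with no calibration attributes, so the
    round-trip is bit-lossless.  Invalid reads (e.g. an empty events list)
    are refused rather than emitted.
    """
    read.validate()
    path = Path(path)
    events_dtype = np.dtype(
        [("model_state", "S5"), ("start", "<i8"), ("length", "<i8"),
         ("move", "<i8")]
    )
    table = np.array(
        [(e.model_state.encode(), e.start, e.length, e.move)
         for e in read.events],
        dtype=events_dtype,
    )
    with h5py.File(path, "w") as h5:
        grp = h5.create_group(f"{_SIGNAL_GROUP}/Read_0")
        grp.create_dataset("Signal", data=np.asarray(read.signal, dtype=np.float64))
        grp.attrs["read_id"] = read.read_id
        for key, value in read.metadata.items():
            grp.attrs[key] = value
        h5.create_dataset(_EVENTS_PATH, data=table)


def index_fast5_dir(directory: str | Path) -> dict[str, Path]:
    """Map read_id -> file path for every parseable Fast5 under ``directory``.

    Files that fail to parse are logged and skipped.  Two files claiming the
    same read_id raise :class:`DuplicateReadError` naming both paths.  Paths
    are visited in lexicographic order, so the mapping is deterministic.
    """
    directory = Path(directory)
    index: dict[str, Path] = {}
    for path in sorted(directory.glob("*.fast5")):
        try:
            read = read_fast5(path)
        except (FormatError, OSError) as exc:
            log.warning("skipping unparseable Fast5 %s: %s", path, exc)
            continue
        if read.read_id in index:
            raise DuplicateReadError(
                f"read_id {read.read_id!r} found in both "
                f"{index[read.read_id]} and {path}"
            )
        index[read.read_id] = path
    return index
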
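import numpy as np
import pytest

from poresig.fast5 import EventRow, NanoporeRead
from poresig.simulate import ClassSpec, make_read, make_site_fixture


@pytest.fixture
def simple_read() -> NanoporeRead:
    """Hand-built 3-event read covering signal[0:30]."""
    signal = np.arange(40, dtype=np.float64)
    events = [
        EventRow("ACGTA", 0, 10, 1),
        EventRow("CGTAC", 10, 8, 1),
        EventRow("GTACG", 18, 12, 1),
    ]
    return NanoporeRead(read_id="readA", signal=signal, events=events)


@pytest.fixture
def stalled_read() -> NanoporeRead:
    """Read whose second event is a stall (move=0) on the first 5-mer."""
    signal = np.arange(23, dtype=np.float64) * 1.5
    events = [
        EventRow("ACGTA", 0, 10, 1),
        EventRow("ACGTA", 10, 5, 0),
        EventRow("CGTAC", 15, 8, 1),
    ]
    return NanoporeRead(read_id="readS", signal=signal, events=events)


@pytest.fixture(scope="session")
def sim_read():
    spec = ClassSpec("test", level_mean=100.0, level_sd=3.0,
                     dwell_min=8, dwell_max=14)
    read, entry = make_read("ACGTACCTGGA", spec, seed=7, stall_prob=0.3)
    return read, entry


@pytest.fixture(scope="session")
def site_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("sitefix")
    fast5_dir, sam_path, bed_path, manifest = make_site_fixture(
        n_reads=9, n_sites=15, seed=11, out_dir=out
    )
    return fast5_dir, sam_path, bed_path, manifest
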
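import numpy as np
import pandas as pd
import pytest

from nidot.containers import ChannelTimeseries, ProbeLayout, default_probe


@pytest.fixture(scope="session")
def single_pair_probe() -> ProbeLayout:
    """One source-detector pair at ~15 mm separation, both wavelengths."""
    probe = default_probe(n_tile_cols=1, n_tile_rows=1)
    tbl = probe.channels
    pair = tbl[(tbl.source == 0) & (tbl.detector == 0)].reset_index(drop=True)
    return ProbeLayout(
        sources=probe.sources,
        detectors=probe.detectors,
        channels=pair,
        wavelengths_nm=probe.wavelengths_nm,
    )


@pytest.fixture(scope="session")
def small_probe() -> ProbeLayout:
    return default_probe(n_tile_cols=2, n_tile_rows=1)


def make_ts(x, rate=4.6, kind="od", distance_mm=30.0, wavelength_nm=850.0):
    """Single- or multi-channel timeseries with a minimal channel table."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    tbl = pd.DataFrame(
        {
            "source": np.zeros(len(x), dtype=int),
            "detector": np.arange(len(x)),
            "wavelength_nm": wavelength_nm,
            "distance_mm": distance_mm,
        }
    )
    return ChannelTimeseries(data=x, rate_hz=rate, channels=tbl, kind=kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
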
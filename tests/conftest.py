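import numpy as np
import pytest
import xarray as xr

from jetcurve import synthio


@pytest.fixture
def harmonic_axis():
    """Single-harmonic meandering axis: A=5 deg, wavelength 60 deg (k=6)."""
    return synthio.JetAxisSpec(base_latitude=45.0, harmonics=((5.0, 6, 0.0),))


@pytest.fixture
def meander_axis():
    """Two-harmonic axis used for detection tests."""
    return synthio.JetAxisSpec(
        base_latitude=45.0, harmonics=((8.0, 2, 0.3), (3.0, 5, 1.2))
    )


@pytest.fixture
def clean_wind(meander_axis):
    """Noise-free single-day wind field on a 1-degree grid."""
    spec = synthio.WindFieldSpec(noise_sd=0.0, spurious_patch_rate=0.0,
                                 grid_step=1.0, n_time=1, seed=0)
    return synthio.generate_wind_field(meander_axis, spec)


def axis_da(y, lon):
    """Wrap a latitude profile as a jet-axis DataArray."""
    return xr.DataArray(np.asarray(y, dtype=float), dims="lon",
                        coords={"lon": np.asarray(lon, dtype=float)},
                        name="axis_latitude")
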
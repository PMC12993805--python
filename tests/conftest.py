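import numpy as np
import pytest

from peatfire.age_depth import fit_age_model
from peatfire.record_io import AgeControlSet, CharcoalSeries
from peatfire.transform import PRSSeries


@pytest.fixture
def linear_controls():
    """Two near-exact controls: 0 cm at 2000 CE, 100 cm at 0 CE."""
    return AgeControlSet(
        site_id="lin",
        depth_cm=np.array([0.0, 100.0]),
        age_ce=np.array([2000.0, 0.0]),
        sd_yr=np.array([1e-12, 1e-12]),
    )


@pytest.fixture
def linear_model(linear_controls):
    return fit_age_model(linear_controls, n_draws=50, seed=0)


@pytest.fixture
def two_segment_controls():
    """0–50 cm over 1000 yr (0.05 cm/yr), 50–100 cm over 3000 yr (0.0167)."""
    return AgeControlSet(
        site_id="two_seg",
        depth_cm=np.array([0.0, 50.0, 100.0]),
        age_ce=np.array([2000.0, 1000.0, -2000.0]),
        sd_yr=np.array([1e-12, 1e-12, 1e-12]),
    )


def make_prs(site_id, ages, values):
    values = np.asarray(values, dtype=float)
    f = int(np.sum(values > 0))
    return PRSSeries(
        site_id=site_id,
        age_ce=np.asarray(ages, dtype=float),
        prs=values,
        f=f,
        n=len(values),
        c_max=float(values.max()) if f else 0.0,
    )


def make_concentration_series(site_id, depth_top, thickness, values):
    depth_top = np.asarray(depth_top, dtype=float)
    return CharcoalSeries(
        site_id=site_id,
        depth_top_cm=depth_top,
        depth_bottom_cm=depth_top + thickness,
        value=np.asarray(values, dtype=float),
    )
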
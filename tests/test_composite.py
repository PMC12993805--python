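import numpy as np
import pytest

from conftest import make_prs
from peatfire.composite import (
    BinnedSeries,
    bin_series,
    bootstrap_composite,
    haversine_km,
    lowess_smooth,
    select_landscape_sites,
    smoother_matrix,
)
from peatfire.record_io import SiteRecord


def binned(site_id, values, starts=None, width=25.0):
    values = np.asarray(values, dtype=float)
    if starts is None:
        starts = width * np.arange(len(values))
    return BinnedSeries(
        site_id=site_id,
        bin_start=np.asarray(starts, dtype=float),
        bin_width=width,
        mean_prs=values,
        n_samples=np.where(np.isfinite(values), 1, 0),
    )


class TestBinning:
    def test_hand_means(self):
        series = make_prs("t", [1905.0, 1910.0, 1930.0], [10.0, 20.0, 60.0])
        out = bin_series(series, bin_width=25.0, origin=0.0, end=2000.0)
        k = int(1900 // 25)
        assert out.mean_prs[k] == pytest.approx(15.0)
        assert out.mean_prs[k + 1] == pytest.approx(60.0)

    def test_one_sample_per_bin_is_identity(self):
        ages = 25.0 * np.arange(10) + 12.5
        vals = np.arange(10, dtype=float)
        out = bin_series(make_prs("t", ages, vals), bin_width=25.0, origin=0.0, end=250.0)
        np.testing.assert_allclose(out.mean_prs, vals)

    def test_empty_bin_is_nan_not_zero(self):
        out = bin_series(make_prs("t", [10.0], [5.0]), bin_width=25.0, origin=0.0, end=100.0)
        assert np.isnan(out.mean_prs[1:]).all()

    def test_sample_conservation(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(-200.0, 2300.0, 500)
        out = bin_series(make_prs("t", ages, np.ones(500)), 25.0, 0.0, 2000.0)
        in_window = np.sum((ages >= 0.0) & (ages < 2000.0))
        assert out.n_samples.sum() == in_window


class TestLowess:
    def test_reproduces_constants(self):
        x = np.arange(0.0, 2000.0, 25.0)
        np.testing.assert_allclose(lowess_smooth(x, np.full(x.size, 7.3)), 7.3)

    def test_reproduces_straight_lines(self):
        x = np.arange(0.0, 2000.0, 25.0)
        y = 0.01 * x - 3.0
        np.testing.assert_allclose(lowess_smooth(x, y), y, atol=1e-9)

    def test_step_smoothing_is_monotone_through_the_step(self):
        x = np.arange(0.0, 2000.0, 25.0)
        y = np.where(x >= 1000.0, 1.0, 0.0)
        sm = lowess_smooth(x, y, window=200.0)
        inside = (x >= 850.0) & (x <= 1150.0)
        assert np.all(np.diff(sm[inside]) >= -1e-12)

    def test_nan_policy(self):
        x = np.arange(10.0)
        y = np.full(10, np.nan)
        assert np.isnan(lowess_smooth(x, y)).all()
        y[3] = 1.0
        y[7] = 1.0
        np.testing.assert_allclose(lowess_smooth(x, y, window=20.0), 1.0)

    def test_matrix_form_matches_function(self):
        rng = np.random.default_rng(1)
        x = 25.0 * np.arange(80)
        y = rng.normal(size=80)
        S = smoother_matrix(x, x, 200.0)
        np.testing.assert_allclose(S @ y, lowess_smooth(x, y, 200.0), atol=1e-12)


class TestBootstrapComposite:
    def test_identical_constant_sites_give_degenerate_band(self):
        group = [binned(f"s{i}", np.full(40, 4.2)) for i in range(5)]
        curve = bootstrap_composite(group, B=200, seed=0)
        np.testing.assert_allclose(curve.mean, 4.2)
        np.testing.assert_allclose(curve.lower, 4.2)
        np.testing.assert_allclose(curve.upper, 4.2)

    def test_two_site_toy_band_enumeration(self):
        """With sites constant at 0 and 10 the only resample means are
        {0, 5, 10}: point mean 5, band within [0, 10]."""
        group = [binned("a", np.zeros(40)), binned("b", np.full(40, 10.0))]
        curve = bootstrap_composite(group, B=1000, seed=3)
        np.testing.assert_allclose(curve.mean, 5.0)
        assert np.all(curve.lower >= 0.0) and np.all(curve.upper <= 10.0)
        assert np.all(curve.lower <= curve.mean) and np.all(curve.mean <= curve.upper)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        group = [binned(f"s{i}", rng.normal(10, 2, 40)) for i in range(6)]
        c1 = bootstrap_composite(group, B=100, seed=9)
        c2 = bootstrap_composite(group[::-1], B=100, seed=9)
        np.testing.assert_array_equal(c1.mean, c2.mean)
        np.testing.assert_array_equal(c1.lower, c2.lower)

    def test_single_site_refused(self):
        with pytest.raises(ValueError, match=">= 2 sites"):
            bootstrap_composite([binned("a", np.ones(10))], B=10, seed=0)

    def test_all_nan_bins_skipped_as_targets(self):
        vals = np.full(40, 2.0)
        vals[10:15] = np.nan
        group = [binned("a", vals), binned("b", vals)]
        curve = bootstrap_composite(group, B=50, seed=0)
        assert len(curve.target_ce) == 35
        assert np.all(np.isfinite(curve.mean))


class TestLandscapeBuffer:
    def _sites(self, *latlon):
        return [
            SiteRecord(site_id=f"s{i}", region="Neotropical", lat=la, lon=lo)
            for i, (la, lo) in enumerate(latlon)
        ]

    def test_haversine_meridian_arc(self):
        # 7.2 deg of latitude along a meridian is ~800.6 km
        assert haversine_km(0.0, -60.0, 7.2, -60.0) == pytest.approx(800.6, abs=0.2)

    def test_colocated_candidate_always_kept(self):
        peat = self._sites((0.0, -60.0))
        cand = self._sites((0.0, -60.0))
        assert select_landscape_sites(peat, cand, radius_km=0.0) == cand

    def test_threshold_exclusion(self):
        peat = self._sites((0.0, -60.0))
        cand = self._sites((7.2, -60.0))  # ~800.6 km away
        assert select_landscape_sites(peat, cand, radius_km=800.0) == []
        assert select_landscape_sites(peat, cand, radius_km=801.0) == cand
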
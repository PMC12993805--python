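import numpy as np
import pytest

from peatfire.composite import bin_series, bootstrap_composite
from peatfire.record_io import read_tables
from peatfire.synthetic import (
    COMPILATION_MIX,
    RegimeSpec,
    SyntheticSite,
    generate_core,
    generate_site_set,
    compilation_preset,
    write_synthetic_dataset,
)
from peatfire.transform import InfluxSeries, prs_transform


def toy_site(**regime_kw):
    return SyntheticSite(
        site_id="T01",
        region="Indomalayan",
        ecosystem="hardwood_swamp",
        lat=2.0,
        lon=102.0,
        elevation_m=20.0,
        footprint=3.0,
        regime=RegimeSpec(**regime_kw),
        true_change_year=regime_kw.get("breaks", ((None, None),))[0][0],
    )


class TestSiteSet:
    def test_forced_rounding(self):
        sites = generate_site_set(4, {"NT": 0.5, "IM": 0.5}, seed=1)
        regions = [s.region for s in sites]
        assert regions.count("Neotropical") == 2
        assert regions.count("Indomalayan") == 2

    def test_paper_split(self):
        sites = generate_site_set(58, COMPILATION_MIX, seed=7)
        counts = {r: sum(1 for s in sites if s.region == r) for r in COMPILATION_MIX}
        assert counts == {
            "Neotropical": 16,
            "Afrotropical": 15,
            "Indomalayan": 16,
            "Australasian": 8,
            "Oceanian": 3,
        }

    def test_determinism(self):
        a = generate_site_set(20, COMPILATION_MIX, seed=42)
        b = generate_site_set(20, COMPILATION_MIX, seed=42)
        assert a == b

    def test_region_default_break_directions(self):
        sites = generate_site_set(58, COMPILATION_MIX, seed=0)
        for s in sites:
            mults = [m for _, m in s.regime.breaks]
            if s.region in ("Indomalayan", "Australasian"):
                assert mults and mults[0] > 1.0
            elif s.region in ("Neotropical", "Afrotropical"):
                assert not mults or mults[0] < 1.0

    def test_invalid_proportions_name_the_label(self):
        with pytest.raises(ValueError, match="NT|Neotropical"):
            generate_site_set(4, {"NT": -0.5, "IM": 1.5}, seed=1)
        with pytest.raises(ValueError, match="sum to 1"):
            generate_site_set(4, {"NT": 0.5, "IM": 0.6}, seed=1)


class TestCore:
    def test_construction_counts(self):
        ctrl, series, truth = generate_core(toy_site(), 100.0, 1.0, 5, 30.0, seed=3)
        assert len(series) == 100 and len(ctrl) == 5
        assert np.all(np.diff(truth.true_age_ce) < 0)  # deeper is older
        assert truth.true_age_ce[0] <= 2000.0

    def test_span_covers_last_three_millennia(self):
        for seed in range(10):
            _, _, truth = generate_core(toy_site(), 100.0, 1.0, 4, 30.0, seed=seed)
            assert truth.ctrl_true_age_ce[0] - truth.ctrl_true_age_ce[-1] >= 3000.0 - 1e-9

    def test_zero_prob_one_gives_all_zero(self):
        _, series, truth = generate_core(
            toy_site(zero_prob=1.0), 50.0, 1.0, 3, 30.0, seed=0
        )
        assert np.all(series.value == 0.0) and np.all(truth.true_influx == 0.0)

    def test_determinism(self):
        a = generate_core(toy_site(), 80.0, 2.0, 4, 25.0, seed=9)
        b = generate_core(toy_site(), 80.0, 2.0, 4, 25.0, seed=9)
        np.testing.assert_array_equal(a[1].value, b[1].value)
        np.testing.assert_array_equal(a[0].age_ce, b[0].age_ce)

    def test_truth_conservation(self):
        """Integrated true influx equals the charcoal mass implied by the
        concentration record, segment by segment."""
        _, series, truth = generate_core(toy_site(), 100.0, 1.0, 5, 30.0, seed=4)
        thickness = series.depth_bottom_cm - series.depth_top_cm
        mass_from_conc = series.value * thickness
        dt = thickness / truth.true_rate_cm_yr
        mass_from_influx = truth.true_influx * dt
        np.testing.assert_allclose(mass_from_conc, mass_from_influx, atol=1e-9)

    def test_break_multiplier_recovered_in_expectation(self):
        """Pooling over many seeds, mean true influx after a ×5 break at
        1900 CE is 5× the pre-break mean (Monte-Carlo of the generator)."""
        site = toy_site(breaks=((1900.0, 5.0),))
        before, after = [], []
        for seed in range(500):
            _, _, truth = generate_core(site, 60.0, 1.0, 3, 30.0, seed=seed)
            post = truth.true_age_ce >= 1900.0
            after.append(truth.true_influx[post])
            before.append(truth.true_influx[~post])
        ratio = np.concatenate(after).mean() / np.concatenate(before).mean()
        assert ratio == pytest.approx(5.0, rel=0.10)

    def test_bad_geometry_refused(self):
        with pytest.raises(ValueError):
            generate_core(toy_site(), -1.0, 1.0, 3, 30.0, seed=0)


class TestPresetAndRecovery:
    def test_written_dataset_round_trips(self, tmp_path):
        paths = write_synthetic_dataset(tmp_path, seed=5, n_sites=10)
        sites, series, controls = read_tables(
            paths["sites"], paths["charcoal"], paths["age_controls"]
        )
        assert len(sites) == 10
        assert set(series) == {s.site_id for s in sites}
        assert (tmp_path / "truth.csv").exists()

    def test_deterministic_serialization(self, tmp_path):
        write_synthetic_dataset(tmp_path / "a", seed=11, n_sites=8)
        write_synthetic_dataset(tmp_path / "b", seed=11, n_sites=8)
        for name in ("sites.csv", "charcoal.csv", "age_controls.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_regime_recovery_in_composite(self):
        """A ×5 break at 1900 CE across 200 sites lifts the composite
        1900–2000 CE mean above the 1800–1900 CE mean in every tried seed."""
        site = toy_site(breaks=((1900.0, 5.0),))
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            binned = []
            for i in range(200):
                _, _, truth = generate_core(site, 80.0, 1.5, 4, 30.0,
                                            seed=int(rng.integers(2**31)))
                prs = prs_transform(
                    InfluxSeries(f"s{i:03d}", truth.true_age_ce, truth.true_influx)
                )
                binned.append(bin_series(prs))
            curve = bootstrap_composite(binned, B=50, seed=seed)
            recent = (curve.target_ce >= 1900.0) & (curve.target_ce < 2000.0)
            prior = (curve.target_ce >= 1800.0) & (curve.target_ce < 1900.0)
            if curve.mean[recent].mean() > curve.mean[prior].mean():
                wins += 1
        assert wins == n_seeds
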
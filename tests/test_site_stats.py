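import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peatfire.site_stats import (
    assign_elevation_group,
    assign_footprint_class,
    kruskal_wallis,
    one_way_anova,
    pca_climate,
    screen_and_regress,
)


class TestGroupings:
    @pytest.mark.parametrize(
        "elev,label",
        [(120, "lowland"), (499.9, "lowland"), (500, "upland"),
         (1500, "upland"), (1500.1, "highland"), (3800, "highland")],
    )
    def test_elevation(self, elev, label):
        assert assign_elevation_group(elev) == label

    @pytest.mark.parametrize(
        "fp,label",
        [(0.5, "wilderness"), (1.0, "intact"), (4.0, "intact"),
         (4.1, "highly_modified"), (17, "highly_modified")],
    )
    def test_footprint(self, fp, label):
        assert assign_footprint_class(fp) == label

    def test_footprint_out_of_range_refused(self):
        with pytest.raises(ValueError):
            assign_footprint_class(51.0)


class TestKruskalWallis:
    def test_hand_rank_computation(self):
        h, p = kruskal_wallis({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert h == pytest.approx(27.0 / 7.0, abs=1e-9)

    def test_identical_groups_give_zero(self):
        h, _ = kruskal_wallis({"A": [1.0, 2.0], "B": [1.0, 2.0]})
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values(self):
        h, p = kruskal_wallis({"A": [3.0, 3.0], "B": [3.0, 3.0]})
        assert (h, p) == (0.0, 1.0)

    def test_label_permutation_invariance(self):
        g = {"A": [1.0, 5.0, 2.0], "B": [4.0, 4.0], "C": [9.0, 0.5]}
        h1, p1 = kruskal_wallis(g)
        h2, p2 = kruskal_wallis({k: g[k] for k in ["C", "A", "B"]})
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_matches_reference_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = {
                chr(65 + i): rng.integers(0, 6, size=rng.integers(3, 10)).astype(float)
                for i in range(int(rng.integers(2, 5)))
            }
            if np.ptp(np.concatenate(list(g.values()))) == 0:
                continue  # scipy refuses the all-identical case
            h, p = kruskal_wallis(g)
            ref = sps.kruskal(*g.values())
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestAnova:
    def test_equal_means_give_zero_f(self):
        f, _ = one_way_anova({"A": [1.0, 2.0], "B": [1.0, 2.0]})
        assert f == pytest.approx(0.0)

    def test_zero_within_variance_convention(self):
        f, p = one_way_anova({"A": [0.0, 0.0], "B": [1.0, 1.0]})
        assert np.isinf(f) and p == 0.0

    def test_hand_sums_of_squares(self):
        f, _ = one_way_anova({"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0]})
        assert f == pytest.approx(1.5)


class TestPCA:
    def _frame(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        return pd.DataFrame(
            {"a": a, "b": 2.0 * a + 1.0, "c": rng.normal(size=n)}
        )

    def test_perfectly_correlated_pair(self):
        df = self._frame()[["a", "b"]]
        _, _, varexp = pca_climate(df, ["a", "b"])
        np.testing.assert_allclose(varexp, [100.0, 0.0], atol=1e-9)

    def test_variance_explained_sums_to_100(self):
        _, _, varexp = pca_climate(self._frame(), ["a", "b", "c"])
        assert varexp.sum() == pytest.approx(100.0)
        assert np.all(np.diff(varexp) <= 1e-12)

    def test_reconstruction(self):
        df = self._frame()
        scores, loadings, _ = pca_climate(df, ["a", "b", "c"])
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(scores @ loadings.to_numpy().T, Z, atol=1e-8)

    def test_duplicating_all_sites_leaves_loadings_unchanged(self):
        df = self._frame()
        _, l1, _ = pca_climate(df, ["a", "b", "c"])
        _, l2, _ = pca_climate(pd.concat([df, df], ignore_index=True), ["a", "b", "c"])
        np.testing.assert_allclose(l1.to_numpy(), l2.to_numpy(), atol=1e-9)

    def test_constant_variable_dropped_with_warning(self):
        df = self._frame()
        df["k"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            _, loadings, _ = pca_climate(df, ["a", "b", "c", "k"])
        assert "k" not in loadings.index


class TestScreenAndRegress:
    def test_response_equal_to_candidate(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        df = pd.DataFrame({"y": y, "x1": y, "x2": rng.normal(size=60)})
        rep = screen_and_regress(df, "y", ["x1", "x2"])
        assert rep.selected == ["x1"]
        assert rep.coefficients["x1"] == pytest.approx(1.0, abs=1e-8)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_weak_candidate_screened_out(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=200)
        weak = 0.1 * y + rng.normal(size=200)  # |r| ~ 0.1 < 0.25
        df = pd.DataFrame({"y": y, "w": weak})
        rep = screen_and_regress(df, "y", ["w"])
        assert rep.screened_in == [] and rep.selected == []

    def test_collinear_pair_drops_weaker(self):
        rng = np.random.default_rng(3)
        n = 800
        z = rng.normal(size=n)
        x1 = z
        x2 = 0.97 * z + np.sqrt(1 - 0.97**2) * rng.normal(size=n)
        y = 0.8 * x1 + 0.8 * rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        rep = screen_and_regress(df, "y", ["x1", "x2"])
        assert rep.dropped_collinear == ["x2"]
        assert rep.selected == ["x1"]

    def test_backward_elimination_keeps_only_significant_terms(self):
        rng = np.random.default_rng(4)
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.5 * x1 + 0.30 * x2 + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        rep = screen_and_regress(df, "y", ["x1", "x2"])
        assert "x1" in rep.selected
        assert all(p < 0.05 for p in rep.pvalues.values())
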
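"""Dataset-level statistics: PCA, ANOVA, correlations, sampling curves,
concordance, left/right tests, CV summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmjmorph import stats as st
from nmjmorph.stats import StatsError


def _factor_frame(rng, n_per=10, n_muscles=9, n_mice=3,
                  muscle_effect=0.0, side_effect=0.0, noise=1.0):
    """A balanced muscle x mouse x side design with optional true effects."""
    rows = []
    muscle_offsets = muscle_effect * np.arange(n_muscles)
    for m in range(n_muscles):
        for j in range(n_mice):
            for s, side in enumerate(("L", "R")):
                y = (muscle_offsets[m] + side_effect * s
                     + rng.normal(0, noise, n_per))
                for i, v in enumerate(y):
                    rows.append({"muscle": f"mus{m}", "mouse": f"M{j}",
                                 "side": side, "nmj": i, "y": v})
    return pd.DataFrame(rows)


class TestPCA:
    def test_rank_one_structure(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = st.pca_core(df, variables=["a", "b"])
        assert res.explained_variance[0] == pytest.approx(100.0)

    def test_independent_variables_share_variance_equally(self, rng):
        cols = {f"v{i}": rng.normal(size=5000) for i in range(11)}
        res = st.pca_core(pd.DataFrame(cols), variables=list(cols))
        assert np.all(np.diff(res.explained_variance) <= 1e-9)
        np.testing.assert_allclose(res.explained_variance,
                                   100 / 11, atol=1.0)

    def test_constant_variable_is_named_error(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.raises(StatsError, match="b"):
            st.pca_core(df, variables=["a", "b"])

    def test_scores_centred_and_reconstruction_exact(self, rng):
        cols = {f"v{i}": rng.normal(size=200) for i in range(5)}
        df = pd.DataFrame(cols)
        res = st.pca_core(df, variables=list(cols))
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        # loadings columns are unit norm
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0, atol=1e-9)
        # full reconstruction of the z-scored data
        Z = (df[list(cols)].to_numpy() - res.mean.to_numpy()) / res.scale.to_numpy()
        back = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(back, Z, atol=1e-8)

    def test_explained_variance_descending_and_bounded(self, rng):
        cols = {f"v{i}": rng.normal(size=100) * (i + 1) for i in range(6)}
        res = st.pca_core(pd.DataFrame(cols), variables=list(cols))
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-9)
        assert np.all((ev >= 0) & (ev <= 100))
        assert ev.sum() <= 100 + 1e-6

    def test_single_record_is_error(self):
        with pytest.raises(StatsError):
            st.pca_core(pd.DataFrame({"a": [1.0], "b": [2.0]}),
                        variables=["a", "b"])


class TestThreeWayAnova:
    def test_detects_muscle_not_side(self, rng):
        df = _factor_frame(rng, n_per=40, muscle_effect=0.5)
        res = st.three_way_anova(df, "y")
        assert res.p("muscle") < 0.001
        assert res.p("side") > 0.05

    def test_null_p_values_uniform(self, rng):
        """Permutation calibration: with a pure-noise response the muscle
        p-value should be uniform over replicates."""
        df = _factor_frame(rng, n_per=4)
        ps = []
        for _ in range(200):
            df["y"] = rng.normal(size=len(df))
            ps.append(st.three_way_anova(df, "y").p("muscle"))
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_response_is_error(self, rng):
        df = _factor_frame(rng, n_per=3)
        df["y"] = 1.0
        with pytest.raises(StatsError):
            st.three_way_anova(df, "y")

    def test_single_level_factor_is_error(self, rng):
        df = _factor_frame(rng, n_per=3)
        df = df[df["side"] == "L"]
        with pytest.raises(StatsError):
            st.three_way_anova(df, "y")

    def test_type_iii_matches_r_car_anova(self, rng):
        """Cross-check type-III sums of squares against R's car::Anova on an
        unbalanced design."""
        pytest.importorskip("subprocess")
        import subprocess
        import tempfile
        from pathlib import Path

        df = _factor_frame(rng, n_per=5, n_muscles=3, muscle_effect=0.8)
        df = df.drop(index=df.index[:7])  # unbalance it
        res = st.three_way_anova(df, "y")
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            df.to_csv(csv, index=False)
            rscript = (
                "suppressMessages(library(car));"
                f"d <- read.csv('{csv}');"
                "d$muscle <- factor(d$muscle); d$mouse <- factor(d$mouse);"
                "d$side <- factor(d$side);"
                "options(contrasts = c('contr.sum', 'contr.poly'));"
                "m <- lm(y ~ muscle + mouse + side, data = d);"
                "a <- Anova(m, type = 3);"
                "cat(a[['Sum Sq']][2:4], a[['Pr(>F)']][2:4])"
            )
            try:
                out = subprocess.run(["Rscript", "-e", rscript],
                                     capture_output=True, text=True,
                                     timeout=120)
            except (FileNotFoundError, subprocess.TimeoutExpired):
                pytest.skip("Rscript unavailable")
            if out.returncode != 0:
                pytest.skip(f"R failed: {out.stderr[:200]}")
            nums = [float(x) for x in out.stdout.split()]
        r_ss, r_p = nums[:3], nums[3:]
        for factor, ss, p in zip(["muscle", "mouse", "side"], r_ss, r_p):
            assert res.table.loc[factor, "sum_sq"] == pytest.approx(ss, rel=1e-6)
            assert res.table.loc[factor, "p"] == pytest.approx(p, rel=1e-6)


class TestDiameterCorrelations:
    def _frame(self, rng, n=2000):
        axon = rng.normal(3.0, 0.5, n)
        fibre = rng.normal(40.0, 8.0, n)
        return pd.DataFrame({
            "axon_diameter": axon,
            "muscle_fibre_diameter": fibre,
            "proportional": 2 * axon,
            "independent": rng.normal(size=n),
        })

    def test_exact_proportionality_gives_r_one(self, rng):
        out = st.diameter_correlations(self._frame(rng),
                                       variables=["proportional"])
        assert out.loc["proportional", "r_axon"] == pytest.approx(1.0)

    def test_independent_variable_near_zero(self, rng):
        out = st.diameter_correlations(self._frame(rng),
                                       variables=["independent"])
        assert abs(out.loc["independent", "r_axon"]) < 0.05
        assert abs(out.loc["independent", "r_fibre"]) < 0.05

    def test_spearman_option(self, rng):
        out = st.diameter_correlations(self._frame(rng),
                                       variables=["proportional"],
                                       method="spearman")
        assert out.loc["proportional", "r_axon"] == pytest.approx(1.0)

    def test_zero_variance_is_error(self, rng):
        df = self._frame(rng, n=100)
        df["flat"] = 5.0
        with pytest.raises(StatsError):
            st.diameter_correlations(df, variables=["flat"])

    def test_all_r_within_bounds(self, rng):
        out = st.diameter_correlations(
            self._frame(rng), variables=["proportional", "independent"])
        assert ((out[["r_axon", "r_fibre"]].abs() <= 1).all()).all()


class TestRunningMean:
    def test_constant_series_flat(self):
        res = st.running_mean_curve([7.0] * 50)
        np.testing.assert_allclose(res.means, 7.0)
        assert res.plateau_deviation == 0.0

    def test_alternating_series_converges_with_1_over_k(self):
        x = [0.0, 1.0] * 50
        res = st.running_mean_curve(x)
        k = np.arange(1, 101)
        assert abs(res.means[-1] - 0.5) < 1e-12
        np.testing.assert_array_less(np.abs(res.means - 0.5), 1.0 / k + 1e-12)

    def test_diagnostic_shrinks_with_sampling(self, rng):
        x = rng.normal(10, 3, 50)
        res = st.running_mean_curve(x)
        # beyond the 30-sample mark the running mean stays near the final mean
        assert res.plateau_deviation < 0.2

    def test_empty_is_error(self):
        with pytest.raises(StatsError):
            st.running_mean_curve([])


class TestInterobserver:
    def _table(self, rng, n=120):
        return pd.DataFrame({
            "muscle": ["m"] * n, "mouse": ["M"] * n, "side": ["L"] * n,
            "nmj": np.arange(n),
            "achr_area": rng.normal(300, 60, n),
            "axon_diameter": rng.normal(3, 0.4, n),
        })

    def test_identical_tables_give_r_one(self, rng):
        a = self._table(rng)
        res = st.interobserver(a, a.copy(),
                               variables=["achr_area", "axon_diameter"])
        np.testing.assert_allclose(res.table["r"], 1.0)

    def test_small_noise_keeps_r_high(self, rng):
        a = self._table(rng)
        b = a.copy()
        b["achr_area"] = b["achr_area"] + rng.normal(
            0, 0.1 * a["achr_area"].std(), len(a))
        res = st.interobserver(a, b, variables=["achr_area"])
        assert res.table.loc["achr_area", "r"] > 0.99

    def test_unrelated_rater_near_zero(self, rng):
        a = self._table(rng)
        b = a.copy()
        b["achr_area"] = rng.normal(300, 60, len(a))
        res = st.interobserver(a, b, variables=["achr_area"])
        assert abs(res.table.loc["achr_area", "r"]) < 0.2

    def test_key_mismatch_is_error(self, rng):
        a = self._table(rng)
        b = a.copy()
        b["nmj"] = b["nmj"] + 1000
        with pytest.raises(StatsError):
            st.interobserver(a, b, variables=["achr_area"])


class TestLeftRight:
    def test_identical_sides_not_significant(self, rng):
        df = _factor_frame(rng, n_per=10, n_muscles=3, n_mice=2)
        piv = df.pivot_table(index=["muscle", "mouse", "nmj"], columns="side",
                             values="y").reset_index()
        piv["R"] = piv["L"]
        df = piv.melt(id_vars=["muscle", "mouse", "nmj"], value_vars=["L", "R"],
                      var_name="side", value_name="y")
        out = st.left_right_tests(df, "y")
        np.testing.assert_allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_true_shift_is_flagged_after_correction(self, rng):
        df = _factor_frame(rng, n_per=40)
        shift = (df["muscle"] == "mus0") & (df["mouse"] == "M0") & (
            df["side"] == "R")
        df.loc[shift, "y"] += 2.0  # 2 SD shift in one pair
        out = st.left_right_tests(df, "y")
        hit = out[(out["muscle"] == "mus0") & (out["mouse"] == "M0")]
        assert bool(hit["significant"].iloc[0])
        assert out["significant"].sum() == 1

    def test_familywise_error_controlled(self, rng):
        """27 null pairs: the family-wise false-positive rate after
        Bonferroni stays at or below the nominal level."""
        n_rep, hits = 300, 0
        for _ in range(n_rep):
            left = rng.normal(size=(27, 20))
            right = rng.normal(size=(27, 20))
            _, p = sps.ttest_ind(left, right, axis=1)
            hits += (p * 27 < 0.05).any()
        rate = hits / n_rep
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_missing_side_is_error(self, rng):
        df = _factor_frame(rng, n_per=5, n_muscles=2, n_mice=1)
        df = df[~((df["muscle"] == "mus0") & (df["side"] == "R"))]
        with pytest.raises(StatsError):
            st.left_right_tests(df, "y")

    def test_bonferroni_never_increases_significance(self, rng):
        df = _factor_frame(rng, n_per=15)
        out = st.left_right_tests(df, "y")
        assert (out["p_bonferroni"] >= out["p"] - 1e-15).all()
        assert out["significant"].sum() <= (out["p"] < 0.05).sum()


class TestCVSummary:
    def _frame(self, rng, values_fn, n_samples=100, n_per=40):
        rows = []
        for s in range(n_samples):  # one synthetic sample per "muscle"
            vals = values_fn(s)
            for i, v in enumerate(vals):
                rows.append({"muscle": f"m{s}", "mouse": "M1",
                             "side": "L", "nmj": i, "x": v})
        return pd.DataFrame(rows)

    def test_constant_within_samples_gives_zero(self, rng):
        df = self._frame(rng, lambda s: np.full(5, s + 1.0), n_samples=20)
        out = st.cv_summary(df, variables=["x"])
        assert out["median_cv"] == 0.0

    def test_lognormal_closed_form(self, rng):
        sigma = 0.3
        expected = np.sqrt(np.exp(sigma**2) - 1)  # = 0.3069
        df = self._frame(rng, lambda s: rng.lognormal(2.0, sigma, 40))
        out = st.cv_summary(df, variables=["x"])
        assert out["median_cv"] == pytest.approx(expected, abs=0.02)
        lo, hi = out["interval"]
        assert lo < expected < hi

    def test_single_record_sample_excluded_with_warning(self, rng):
        df = self._frame(rng, lambda s: rng.lognormal(2.0, 0.3, 10),
                         n_samples=6)
        lone = pd.DataFrame([{"muscle": "solo", "mouse": "MX", "side": "L",
                              "nmj": 0, "x": 1.0}])
        with pytest.warns(UserWarning, match="single-record"):
            out = st.cv_summary(pd.concat([df, lone]), variables=["x"])
        assert out["n_cvs"] == 6


class TestTableValidation:
    def test_duplicate_keys_rejected(self, rng):
        df = _factor_frame(rng, n_per=2, n_muscles=1, n_mice=1)
        dup = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(StatsError, match="duplicated"):
            st.validate_table(dup)

    def test_sample_size_warnings(self, rng):
        df = _factor_frame(rng, n_per=20, n_muscles=2, n_mice=1)
        low = st.sample_size_warnings(df)
        assert len(low) == 4  # every (muscle, mouse, side) group has 20 < 30
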
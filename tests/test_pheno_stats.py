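"""Surrounding statistics: per-day tests, ANOVA, IQR, windows, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import wsigomp as w
from wsigomp.growth_core import CONTROL, DROUGHT, PlantTrajectory
from wsigomp.pheno_stats import (
    bonferroni_threshold,
    derived_ratio_traits,
    evaluate_predictions,
    iqr_outlier_flags,
    sliding_spearman,
    timepoint_anova,
    timepoint_ttests,
)


def _make_plants(values_by_treatment, accessions=None):
    """values_by_treatment: dict treatment -> (plants x days) array."""
    out = []
    for treat, mat in values_by_treatment.items():
        for i, row in enumerate(np.atleast_2d(mat)):
            acc = accessions[i] if accessions else f"a{i}"
            out.append(
                PlantTrajectory(
                    accession=acc, experiment="e1", treatment=treat,
                    psa=np.abs(row), fc=np.clip(row / max(np.abs(row).max(), 1), 0, 1),
                )
            )
    return out


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 21, 0.05 / 21), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_values(self, alpha, n, expected):
        thr = bonferroni_threshold(alpha, n)
        assert thr == pytest.approx(expected)
        assert thr * n == pytest.approx(alpha)

    def test_printed_two_significant_figures(self):
        assert float(f"{bonferroni_threshold(0.05, 21):.2g}") == 0.0024


class TestTimepointTtests:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(8, 5))
        plants = _make_plants({CONTROL: base, DROUGHT: base})
        res = timepoint_ttests(plants, "psa")
        assert len(res) == 5
        assert res["p_value"].min() > 0.99
        assert not res["significant"].any()

    def test_huge_effect_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(50, 3)) + 20
        b = rng.normal(5, 1, size=(50, 3)) + 20
        plants = _make_plants({CONTROL: a, DROUGHT: b})
        res = timepoint_ttests(plants, "psa")
        assert res["significant"].all()

    def test_matches_scipy_welch(self, small_trajectories):
        res = timepoint_ttests(small_trajectories, "fc")
        xc = np.array([tr.fc for tr in small_trajectories if tr.treatment == CONTROL])
        xd = np.array([tr.fc for tr in small_trajectories if tr.treatment == DROUGHT])
        day = 10
        want = stats.ttest_ind(xc[:, day - 1], xd[:, day - 1], equal_var=False)
        row = res[res["day"] == day].iloc[0]
        assert row["p_value"] == pytest.approx(want.pvalue)

    def test_fc_separates_treatments_from_second_day(self, small_trajectories):
        """Drought pots dry down, so FC differs early at the corrected
        threshold — the hallmark pattern of a withheld-water design."""
        res = timepoint_ttests(small_trajectories, "fc")
        assert not res[res["day"] == 1]["significant"].iloc[0]
        assert res[res["day"] >= 2]["significant"].all()


class TestTimepointAnova:
    def _replicated(self, interaction=0.0, seed=0, n_acc=6, n_rep=3, D=2):
        rng = np.random.default_rng(seed)
        plants = []
        for i in range(n_acc):
            for treat in (CONTROL, DROUGHT):
                for _ in range(n_rep):
                    shift = interaction * i * (treat == DROUGHT)
                    vals = 50 + 5 * i + 10 * (treat == DROUGHT) + shift
                    psa = vals + rng.normal(0, 1, size=D)
                    plants.append(
                        PlantTrajectory(
                            accession=f"a{i}", experiment="e1", treatment=treat,
                            psa=np.abs(psa), fc=np.full(D, 0.5),
                        )
                    )
        return plants

    def test_interaction_detected(self):
        res = timepoint_anova(self._replicated(interaction=8.0, seed=1))
        assert (res["p_interaction"] < 0.001).all()

    def test_null_interaction_p_uniform(self):
        """Without a true interaction the per-day interaction p-value is
        approximately uniform across replicate simulations."""
        ps = []
        for seed in range(40):
            res = timepoint_anova(self._replicated(interaction=0.0, seed=seed, D=1))
            ps.append(res["p_interaction"].iloc[0])
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_balanced_type1_matches_type3(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        plants = self._replicated(interaction=4.0, seed=3, D=1)
        res = timepoint_anova(plants)
        df = pd.DataFrame(
            {
                "value": [tr.psa[0] for tr in plants],
                "accession": [tr.accession for tr in plants],
                "treatment": [tr.treatment for tr in plants],
            }
        )
        model = smf.ols(
            "value ~ C(treatment) + C(accession) + C(treatment):C(accession)", df
        ).fit()
        t3 = sm.stats.anova_lm(model, typ=3)
        assert res["p_interaction"].iloc[0] == pytest.approx(
            t3.loc["C(treatment):C(accession)", "PR(>F)"]
        )

    def test_unreplicated_interaction_inestimable(self):
        plants = self._replicated(interaction=0.0, seed=4, n_rep=1, D=1)
        res = timepoint_anova(plants)
        assert res["p_interaction"].isna().all()


class TestIqrFlags:
    def test_hand_example(self):
        flags = iqr_outlier_flags([1, 2, 3, 4, 100])
        np.testing.assert_array_equal(flags, [False] * 4 + [True])

    def test_constant_vector_no_flags(self):
        assert not iqr_outlier_flags(np.full(10, 3.0)).any()

    def test_symmetric_data_no_flags(self):
        assert not iqr_outlier_flags(np.linspace(0, 1, 20)).any()

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning):
            flags = iqr_outlier_flags([1.0, 2.0, 50.0])
        assert not flags.any()

    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 1e3),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, deadline=None)
    def test_affine_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        x[0] += 10  # ensure something interesting
        np.testing.assert_array_equal(
            iqr_outlier_flags(x), iqr_outlier_flags(shift + scale * x)
        )


class TestSlidingSpearman:
    def test_perfect_monotone(self):
        daily = np.tile(np.arange(10.0)[:, None], (1, 5))
        y = np.arange(10.0)
        res = sliding_spearman(daily, y, window=3)
        assert len(res) == 3
        np.testing.assert_allclose(res["rho"], 1.0, atol=1e-12)
        res_rev = sliding_spearman(daily, y[::-1].copy(), window=3)
        np.testing.assert_allclose(res_rev["rho"], -1.0, atol=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        """Windowed Spearman equals ranking the window means and taking
        Pearson's r, on random instances (including ties)."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            daily = rng.integers(0, 5, size=(15, 8)).astype(float)
            y = rng.integers(0, 4, size=15).astype(float)
            res = sliding_spearman(daily, y, window=3)
            for row in res.itertuples(index=False):
                xm = daily[:, row.day_start - 1 : row.day_end].mean(axis=1)
                want = stats.pearsonr(stats.rankdata(xm), stats.rankdata(y)).statistic
                assert row.rho == pytest.approx(want, abs=1e-12)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            sliding_spearman(np.zeros((4, 3)), np.zeros(4), window=5)


class TestEvaluatePredictions:
    def test_exact_prediction(self):
        obs = np.arange(12.0).reshape(3, 4) + 1
        res = evaluate_predictions(obs, obs)
        np.testing.assert_allclose(res["pearson_r"], 1.0, atol=1e-12)
        assert (res["rmse"] == 0.0).all()
        assert (res["rrmse"] == 0.0).all()

    def test_hand_arithmetic(self):
        res = evaluate_predictions(np.array([[9.0], [11.0]]), np.array([[10.0], [10.0]]))
        row = res.iloc[0]
        assert row["rmse"] == pytest.approx(1.0)
        assert row["rrmse"] == pytest.approx(0.1)

    def test_shift_invariance_of_r(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(size=(20, 3))
        obs = pred + rng.normal(0, 0.5, size=(20, 3))
        r1 = evaluate_predictions(pred, obs)["pearson_r"]
        r2 = evaluate_predictions(pred + 7.0, obs)["pearson_r"]
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_zero_variance_reported_missing(self):
        res = evaluate_predictions(np.full((5, 1), 2.0), np.random.default_rng(0).normal(size=(5, 1)))
        assert np.isnan(res["pearson_r"].iloc[0])


class TestDerivedRatios:
    def test_identical_trajectories_ratio_one(self):
        mat = np.full((3, 4), 50.0)
        plants = _make_plants({CONTROL: mat, DROUGHT: mat})
        res = derived_ratio_traits(plants)
        assert (res["ratio"] == 1.0).all()

    def test_half_control(self):
        mat = np.full((2, 4), 80.0)
        plants = _make_plants({CONTROL: mat, DROUGHT: mat * 0.5})
        res = derived_ratio_traits(plants)
        assert (res["ratio"] == 0.5).all()

    def test_missing_treatment_excluded(self):
        plants = _make_plants({CONTROL: np.full((2, 3), 10.0)})
        plants.append(
            PlantTrajectory(accession="a0", experiment="e1", treatment=DROUGHT,
                            psa=np.full(3, 5.0), fc=np.full(3, 0.5))
        )
        res = derived_ratio_traits(plants)
        assert set(res["accession"]) == {"a0"}
        assert res.attrs["n_excluded"] == 1
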
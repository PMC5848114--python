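"""Correlation, age-trend, ICC reliability, and difference summaries."""

import numpy as np
import pandas as pd
import pytest

from tcmbmd import (
    age_trend,
    difference_summary,
    icc_3_1_consistency,
    pearson,
    synthetic_cohort,
)

# printed validation vectors for the seven-vial experiment (g/cm^3)
REAL_VIALS = [0.135, 0.202, 0.267, 0.300, 0.344, 0.401, 0.467]
CALC_VIALS = [0.143, 0.215, 0.276, 0.306, 0.363, 0.407, 0.468]


def brute_force_icc31(table: np.ndarray) -> float:
    """Independent two-way ANOVA oracle: cell-by-cell sums of squares."""
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].sum() / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (table[:, j].sum() / n - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            resid = table[i, j] - table[i].mean() - table[:, j].mean() + grand
            ss_err += resid**2
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestPearson:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = pearson(x, 2 * x + 1)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_orthogonal_residuals_give_zero_r(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson(x, y).pearson_r == pytest.approx(0.0, abs=1e-12)

    def test_five_point_example(self):
        fit = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert fit.pearson_r == pytest.approx(0.8)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r0 = pearson(x, y).pearson_r
        assert pearson(3.2 * x + 7, y).pearson_r == pytest.approx(r0, abs=1e-12)
        assert pearson(x, 0.5 * y - 2).pearson_r == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAgeTrend:
    def test_loss_rate_definition(self):
        """Constructed cohort with slope -0.0015 g/cm^3/yr around mean 0.166."""
        ages = np.linspace(35.0, 59.0, 9)
        vbmd = 0.166 - 0.0015 * (ages - ages.mean())
        df = pd.DataFrame({"sex": "female", "age": ages, "vbmd": vbmd})
        fit, loss = age_trend(df)
        assert fit.slope == pytest.approx(-0.0015)
        assert loss == pytest.approx(-(-0.0015) / 0.166 * 100.0, rel=1e-6)
        assert loss == pytest.approx(0.9036, abs=1e-3)

    def test_zero_slope_cohort(self):
        # symmetric residuals: least-squares slope is exactly zero
        df = pd.DataFrame(
            {"sex": "male", "age": [30.0, 45.0, 60.0], "vbmd": [0.2, 0.21, 0.2]}
        )
        fit, loss = age_trend(df)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_constant_vbmd_rejected(self):
        df = pd.DataFrame(
            {"sex": "male", "age": [30.0, 45.0, 60.0, 70.0], "vbmd": [0.2] * 4}
        )
        with pytest.raises(ValueError, match="zero variance"):
            age_trend(df)

    def test_sex_filter_and_recovery(self):
        """Female subset generated at r = -0.615 recovers a clearly negative
        correlation at n = 11."""
        rng = np.random.default_rng(11)
        females = synthetic_cohort(11, rng, sex="female")
        males = synthetic_cohort(17, rng, sex="male", age_range=(30, 69), age_r=-0.22)
        df = pd.concat([females, males], ignore_index=True)
        fit, loss = age_trend(df, sex="female")
        assert fit.n == 11
        assert fit.pearson_r < -0.2
        assert loss > 0.0

    def test_explicit_baseline(self):
        ages = np.array([40.0, 50.0, 60.0])
        df = pd.DataFrame({"sex": "f", "age": ages, "vbmd": 0.3 - 0.001 * ages})
        _, loss = age_trend(df, baseline=0.2)
        assert loss == pytest.approx(0.001 / 0.2 * 100)


class TestICC:
    def test_identical_raters(self):
        t = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_3_1_consistency(t)
        assert res.icc == pytest.approx(1.0)

    def test_constant_offset_is_ignored(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.16, 0.03, size=12)
        t = np.column_stack([a, a + 0.05])
        res = icc_3_1_consistency(t)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_offset_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(9, 3))
        base = icc_3_1_consistency(t).icc
        shifted = t + np.array([1.0, -2.0, 0.3])  # per-rater constants
        assert icc_3_1_consistency(shifted).icc == pytest.approx(base, abs=1e-10)
        assert icc_3_1_consistency(4.2 * t).icc == pytest.approx(base, abs=1e-10)

    @pytest.mark.parametrize("shape", [(6, 2), (12, 2), (9, 3)])
    def test_matches_brute_force_anova(self, shape):
        rng = np.random.default_rng(sum(shape))
        t = rng.normal(size=shape)
        res = icc_3_1_consistency(t)
        assert res.icc == pytest.approx(brute_force_icc31(t), abs=1e-10)

    def test_matches_pingouin_with_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        truth = rng.normal(0.166, 0.025, size=15)
        t = truth[:, None] + rng.normal(0.0, 0.008, size=(15, 2))
        res = icc_3_1_consistency(t)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["a", "b"], 15),
                "score": t.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        mask = ref["Type"].isin(["ICC3", "ICC(C,1)"])  # label varies by version
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin rounds its CI bounds to two decimals
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=6e-3)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_missing_cells_rejected(self):
        t = np.ones((6, 2))
        t[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_3_1_consistency(t)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1_consistency(np.ones((3, 2)))


class TestDifferenceSummary:
    def test_identity(self):
        res = difference_summary(REAL_VIALS, REAL_VIALS)
        assert res.mean_abs_diff == 0.0
        assert res.max_abs_diff == 0.0

    def test_published_vial_vectors(self):
        res = difference_summary(REAL_VIALS, CALC_VIALS)
        assert res.max_abs_diff == pytest.approx(0.019, abs=1e-12)
        assert round(res.mean_abs_diff, 3) == 0.009

    def test_single_pair(self):
        res = difference_summary([0.1], [0.12])
        assert res.mean_abs_diff == pytest.approx(0.02)
        assert res.max_abs_diff == pytest.approx(0.02)
        assert res.per_item_diff[0] == pytest.approx(0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            difference_summary([0.1, 0.2], [0.1])


class TestParameterRecovery:
    def test_slope_within_two_se_in_93_of_100_replicates(self):
        """Seeded replicates: the fitted age slope covers the generating
        slope within two standard errors at the nominal ~95% rate."""
        rng = np.random.default_rng(123)
        true_slope_hits = 0
        for _ in range(100):
            cohort = synthetic_cohort(20, rng, age_r=-0.5)
            ages = cohort["age"].to_numpy()
            # generating slope implied by the correlation construction
            true_slope = -0.5 * 0.025 / ages.std()
            fit = pearson(ages, cohort["vbmd"].to_numpy())
            if abs(fit.slope - true_slope) < 2 * fit.stderr:
                true_slope_hits += 1
        assert true_slope_hits >= 93
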
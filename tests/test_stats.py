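"""Cohort statistics: GOF, split-plot ANOVA + Scheffé, PCA, chi-squared,
period assignment."""

import numpy as np
import pandas as pd
import pytest

from femora import (
    assign_periods,
    chi_squared_independence,
    normality_gof,
    pca_on_means,
    rm_anova_scheffe,
)
from femora.datasets import hegi_radiocarbon, lateral_curvature_counts


def make_cohort_table(rng, sizes=(10, 10, 5), n_levels=8, shift=None, sd_subj=0.7, sd_noise=0.714):
    """Balanced tidy table with a per-level trend; optional cohort shifts."""
    shift = shift or {}
    rows = []
    for g, n in zip("abc", sizes):
        for i in range(n):
            base = rng.normal(0.0, sd_subj) + shift.get(g, 0.0)
            for level in range(1, n_levels + 1):
                rows.append(
                    (f"{g}{i}", g, level, base + 0.3 * level + rng.normal(0, sd_noise))
                )
    return pd.DataFrame(rows, columns=["specimen_id", "cohort", "level", "value"])


class TestNormalityGof:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(42)
        p = [normality_gof(rng.normal(size=1000)).p for _ in range(100)]
        assert np.mean(np.array(p) > 0.05) >= 0.90

    def test_exponential_samples_mostly_fail(self):
        rng = np.random.default_rng(42)
        p = [normality_gof(rng.exponential(size=1000)).p for _ in range(100)]
        assert np.mean(np.array(p) < 0.05) >= 0.90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normality_gof(np.ones(50))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            normality_gof(np.arange(5))


class TestRmAnovaScheffe:
    def test_ss_decomposition_sums_to_total(self):
        res = rm_anova_scheffe(make_cohort_table(np.random.default_rng(0)))
        t = res.table
        parts = t.loc[
            ["cohort", "subjects_within_cohort", "level", "cohort_x_level", "error_within"],
            "ss",
        ].sum()
        assert parts == pytest.approx(t.loc["total", "ss"], rel=1e-10)
        assert (
            t.loc[t.index != "total", "df"].sum() == t.loc["total", "df"]
        )

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        df = make_cohort_table(np.random.default_rng(1), shift={"c": 1.0})
        res = rm_anova_scheffe(df)
        ref = pg.mixed_anova(
            df, dv="value", within="level", subject="specimen_id", between="cohort"
        ).set_index("Source")
        assert res.table.loc["cohort", "F"] == pytest.approx(ref.loc["cohort", "F"])
        assert res.table.loc["level", "F"] == pytest.approx(ref.loc["level", "F"])
        assert res.table.loc["cohort_x_level", "F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert res.table.loc["cohort", "p"] == pytest.approx(ref.loc["cohort", "p_unc"])

    def test_identical_cohorts_not_significant(self):
        rng = np.random.default_rng(2)
        base = make_cohort_table(rng, sizes=(8,), n_levels=6)
        dup = base.copy()
        dup["cohort"] = "b"
        dup["specimen_id"] = dup["specimen_id"] + "_b"
        both = pd.concat([base, dup], ignore_index=True)
        res = rm_anova_scheffe(both)
        assert res.table.loc["cohort", "F"] == pytest.approx(0.0, abs=1e-20)
        assert not res.scheffe["significant"].any()

    def test_planted_shift_detected(self):
        res = rm_anova_scheffe(
            make_cohort_table(np.random.default_rng(3), shift={"c": 2.0})
        )
        assert res.table.loc["cohort", "p"] < 0.05
        sig = res.scheffe[res.scheffe["significant"]]
        assert {"c"} <= set(sig["cohort_a"]) | set(sig["cohort_b"])

    def test_scheffe_never_more_liberal_than_unadjusted_F(self):
        from scipy import stats as sps

        for seed in range(5):
            res = rm_anova_scheffe(
                make_cohort_table(np.random.default_rng(seed), shift={"b": 0.5})
            )
            df1 = int(res.table.loc["cohort", "df"])
            df2 = int(res.table.loc["subjects_within_cohort", "df"])
            unadjusted_crit = sps.f.isf(res.alpha, 1, df2)
            assert (res.scheffe["critical_value"] >= unadjusted_crit - 1e-12).all()

    def test_missing_levels_dropped_listwise(self):
        df = make_cohort_table(np.random.default_rng(4))
        df = df[~((df.specimen_id == "a0") & (df.level == 3))]
        with pytest.warns(UserWarning, match="missing levels"):
            res = rm_anova_scheffe(df)
        assert "a0" in res.dropped_specimens

    def test_greenhouse_geisser_weakens_within_test(self):
        df = make_cohort_table(np.random.default_rng(5))
        plain = rm_anova_scheffe(df)
        gg = rm_anova_scheffe(df, greenhouse_geisser=True)
        assert gg.table.loc["level", "p"] >= plain.table.loc["level", "p"]


class TestPCA:
    def test_orthonormal_loadings_and_trace(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        res = pca_on_means(X)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_correlated_pair_loads_equally(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=400)
        X = pd.DataFrame(
            {
                "u": base + rng.normal(0, 0.05, 400),
                "v": base + rng.normal(0, 0.05, 400),
                "w": rng.normal(size=400),
            }
        )
        res = pca_on_means(X)
        l1 = res.loadings["Z1"]
        assert l1["u"] == pytest.approx(l1["v"], rel=0.02)

    def test_scores_reconstruct_scaled_data(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        res = pca_on_means(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            pca_on_means(X)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(25, 4)))
        l1 = pca_on_means(X).loadings
        l2 = pca_on_means(X * -1.0).loadings  # flipped data, same correlations
        for comp in l1.columns:
            assert l1[comp].abs().idxmax() == l2[comp].abs().idxmax()
            assert l1.loc[l1[comp].abs().idxmax(), comp] > 0


class TestChiSquared:
    def test_matches_hand_computation_on_published_table(self):
        counts = lateral_curvature_counts().to_numpy(dtype=float)
        with pytest.warns(UserWarning, match="expected counts"):
            res = chi_squared_independence(counts)
        # independent spreadsheet-style computation
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        expected = row * col / counts.sum()
        by_hand = ((counts - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(by_hand, abs=1e-12)
        assert res.df == 6
        assert res.p < 0.05

    def test_proportional_rows_give_zero_statistic(self):
        table = np.array([[10, 20, 30], [5, 10, 15]])
        res = chi_squared_independence(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_uniform_2x2_gives_zero(self):
        res = chi_squared_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0

    def test_all_zero_columns_dropped(self):
        res = chi_squared_independence([[5, 0, 5], [2, 0, 8]])
        assert res.df == 1

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_independence([[3, 4, 5]])


class TestAssignPeriods:
    def test_published_specimens_split_ten_five(self):
        assigned = assign_periods(hegi_radiocarbon())
        counts = assigned["group"].value_counts()
        assert counts["initial_early_jomon"] == 10
        assert counts["late_jomon"] == 5

    def test_period_label_agreement(self):
        data = hegi_radiocarbon()
        assigned = assign_periods(data).set_index("specimen_id")
        labels = data.groupby("specimen_id")["period_label"].first()
        for sid, label in labels.items():
            expected = (
                "late_jomon" if label == "Late Jomon" else "initial_early_jomon"
            )
            assert assigned.loc[sid, "group"] == expected

    def test_boundary_midpoints(self):
        df = pd.DataFrame(
            {
                "specimen_id": ["x", "y"],
                "cal_bp_from": [4350, 7050],
                "cal_bp_to": [4250, 6950],
                "probability_pct": [68.3, 68.3],
            }
        )
        out = assign_periods(df).set_index("specimen_id")
        assert out.loc["x", "group"] == "late_jomon"
        assert out.loc["y", "group"] == "initial_early_jomon"

    def test_out_of_range_age_warns_but_assigns(self):
        df = pd.DataFrame(
            {
                "specimen_id": ["z"],
                "cal_bp_from": [5600],
                "cal_bp_to": [5400],
                "probability_pct": [68.3],
            }
        )
        with pytest.warns(UserWarning, match="outside"):
            out = assign_periods(df)
        assert out.loc[0, "group"] == "late_jomon"
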
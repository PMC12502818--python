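"""Adjusted models, partial correlations, Brown's method, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysbiome.assoc import (
    browns_combine,
    correlation_scan,
    fit_adjusted_lm,
    group_tests,
    partial_correlation,
)
from dysbiome.coredata import CohortMetadata, DysbiomeError, clr_transform
from dysbiome.synthcohort import SimulationConfig, simulate_cohort


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = partial_correlation(x, y, None, "pearson")
        assert rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_identical_vectors_give_rho_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        Z = rng.normal(size=(25, 2))
        rho, p = partial_correlation(x, x.copy(), Z, "pearson")
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_pearson_matches_residualise_then_correlate(self):
        rng = np.random.default_rng(2)
        n = 20
        Z = rng.normal(size=(n, 2))
        x = Z @ [0.5, -0.3] + rng.normal(size=n)
        y = Z @ [0.2, 0.7] + 0.4 * x + rng.normal(size=n)
        rho, _ = partial_correlation(x, y, Z, "pearson")
        D = np.column_stack([np.ones(n), Z])

        def resid(v):
            beta, *_ = np.linalg.lstsq(D, v, rcond=None)
            return v - D @ beta

        oracle = np.corrcoef(resid(x), resid(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_spearman_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n = 40
        df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n),
                           "z": rng.normal(size=n)})
        rho, p = partial_correlation(df["x"], df["y"], df[["z"]], "spearman")
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_too_few_observations_rejected(self):
        with pytest.raises(DysbiomeError):
            partial_correlation(np.ones(4), np.ones(4), np.ones((4, 2)))


class TestBrownsMethod:
    def test_zero_correlation_reduces_to_fisher(self):
        p = np.array([0.02, 0.3, 0.6])
        fisher = stats.chi2.sf(-2 * np.log(p).sum(), 2 * len(p))
        assert browns_combine(p, np.zeros((3, 3))) == pytest.approx(fisher)
        assert browns_combine(p, None) == pytest.approx(fisher)

    @pytest.mark.parametrize("p_single", [0.01, 0.05])
    def test_perfectly_dependent_tests_return_single_p(self, p_single):
        p = np.array([p_single] * 3)
        combined = browns_combine(p, np.ones((3, 3)))
        assert combined == pytest.approx(p_single, rel=0.1)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, 4)
            R = np.eye(4)
            r = rng.uniform(-0.3, 0.9)
            R[0, 1] = R[1, 0] = r
            out = browns_combine(p, R)
            assert 0.0 <= out <= 1.0

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = browns_combine(np.array([0.0, 0.5]), np.zeros((2, 2)))
        assert 0.0 <= out <= 1.0


class TestGroupTests:
    def test_two_group_ranksum_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        v = rng.permutation(np.arange(20.0))  # tie-free
        g = np.repeat(["a", "b"], 10)
        res = group_tests(v, g)
        row = res[res["test"] == "wilcoxon_ranksum"].iloc[0]
        ref = stats.mannwhitneyu(v[g == "a"], v[g == "b"],
                                 alternative="two-sided")
        assert row["p"] == pytest.approx(ref.pvalue)

    def test_location_shift_detected_with_high_power(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            res = group_tests(np.concatenate([a, b]),
                              np.repeat(["a", "b"], 50))
            hits += res["p"].iloc[0] <= 0.05
        assert hits / 50 > 0.9

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            v = rng.normal(size=40)
            res = group_tests(v, np.repeat(["a", "b"], 20))
            ps.append(res["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_three_groups_include_kruskal_omnibus(self):
        rng = np.random.default_rng(8)
        res = group_tests(rng.normal(size=30), np.repeat(list("abc"), 10))
        assert "kruskal" in set(res["test"])
        assert (res["test"] == "wilcoxon_ranksum").sum() == 3

    def test_paired_design_uses_paired_t(self):
        rng = np.random.default_rng(9)
        pre = rng.normal(size=15)
        post = pre + 1 + rng.normal(0, 0.3, 15)
        v = np.concatenate([pre, post])
        g = np.repeat(["pre", "post"], 15)
        pairing = np.concatenate([np.arange(15), np.arange(15)])
        res = group_tests(v, g, paired=pairing)
        assert res["test"].iloc[0] == "paired_t"
        ref = stats.ttest_rel(pre, post)
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(DysbiomeError):
            group_tests(np.ones(3), np.array(["a", "a", "a"]))


class TestAdjustedLm:
    def _meta(self, n, rng, balanced=True):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "subject_id": [f"s{i}" for i in range(n)],
            "diagnosis": rng.choice(["Control", "CD", "UC"], n),
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(45, 10, n),
            "bmi": rng.normal(25, 4, n),
            "marker": rng.normal(size=n)})

    def test_balanced_covariates_leave_group_effect_unchanged(self):
        rng = np.random.default_rng(10)
        n = 3000
        meta = self._meta(n, rng)
        y = (meta["diagnosis"] == "CD") * 1.5 + rng.normal(size=n)
        res = fit_adjusted_lm(pd.Series(y), CohortMetadata(meta),
                              stepwise=False)
        raw = y[meta["diagnosis"] == "CD"].mean() - y[meta["diagnosis"] == "Control"].mean()
        got = res.contrasts.set_index("comparison").loc["CD-Control", "estimate"]
        assert got == pytest.approx(raw, abs=0.1)

    def test_interaction_slope_contrast_matches_per_group_ols(self):
        rng = np.random.default_rng(11)
        n = 600
        meta = self._meta(n, rng)
        slopes = {"Control": 0.0, "CD": 2.0, "UC": 0.5}
        y = np.array([slopes[d] for d in meta["diagnosis"]]) * meta["marker"] \
            + rng.normal(size=n)
        res = fit_adjusted_lm(pd.Series(y), CohortMetadata(meta),
                              phenotype="marker", stepwise=False)
        slope_rows = res.contrasts[res.contrasts["kind"] == "slope"]
        got = slope_rows.set_index("comparison").loc["CD-Control", "estimate"]
        # per-group OLS slopes on the residualised response
        from dysbiome.assoc import _residualize
        resid = _residualize(pd.Series(y), meta)
        per_group = {}
        for lv in ("Control", "CD"):
            m = (meta["diagnosis"] == lv).to_numpy()
            per_group[lv] = np.polyfit(meta["marker"][m], resid[m], 1)[0]
        assert got == pytest.approx(per_group["CD"] - per_group["Control"],
                                    abs=1e-8)

    def test_noise_phenotype_dropped_by_stepwise(self):
        rng = np.random.default_rng(12)
        drops = 0
        for _ in range(25):
            meta = self._meta(250, rng)
            y = (meta["diagnosis"] == "CD") * 1.0 + rng.normal(size=250)
            res = fit_adjusted_lm(pd.Series(y), CohortMetadata(meta),
                                  phenotype="marker", stepwise=True)
            drops += "phenotype" not in res.terms
        assert drops >= 0.8 * 25

    def test_reduces_to_anova_without_covariate_effects(self):
        rng = np.random.default_rng(13)
        n = 400
        meta = self._meta(n, rng)
        y = rng.normal(size=n) + (meta["diagnosis"] == "UC") * 0.8
        res = fit_adjusted_lm(pd.Series(y), CohortMetadata(meta),
                              stepwise=False)
        groups = [y[meta["diagnosis"] == lv] for lv in ("Control", "CD", "UC")]
        f_ref, p_ref = stats.f_oneway(*groups)
        # the two-stage residualisation perturbs the response only slightly
        # when covariates are independent of the group
        assert res.model.fvalue == pytest.approx(f_ref, rel=0.25)


class TestCorrelationScan:
    def test_scan_flags_coupled_taxon_and_orders_columns(self):
        cohort = simulate_cohort(SimulationConfig(seed=21, n_families=60))
        clr = clr_transform(cohort.counts)
        scan = correlation_scan(clr, cohort.metadata, ["ASCA_IgA"])
        assert {"taxon_id", "phenotype", "rho_spearman", "brown_p",
                "brown_p_fdr"} <= set(scan.columns)
        assert (scan["brown_p_fdr"] >= scan["brown_p"] - 1e-12).all()
        # disease-up taxa couple to the dysbiosis-driven biomarker
        up = [t for t, fc in zip(cohort.counts.taxon_ids,
                                 cohort.truth["log2fc"]) if fc > 0]
        sig = set(scan.loc[scan["brown_p_fdr"] <= 0.05, "taxon_id"])
        assert len(sig & set(up)) >= len(up) // 2

    def test_brown_p_not_far_below_smallest_input(self):
        cohort = simulate_cohort(SimulationConfig(seed=22, n_families=30))
        clr = clr_transform(cohort.counts)
        scan = correlation_scan(clr, cohort.metadata, ["BSS"])
        pmin = scan[["p_pearson", "p_spearman", "p_kendall"]].min(axis=1)
        assert (scan["brown_p"] >= pmin / 3.0 - 1e-12).all()
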
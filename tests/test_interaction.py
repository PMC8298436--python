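"""Mixed-model machinery: fitter correctness, nulls, LRT, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mprastat as m
from mprastat.errors import InsufficientDataError
from mprastat.interaction import (
    _profile_fit,
    _snp_long_data,
    _SuffStats,
    Thresholds,
)


def _expr_for(n_snps=3, seed=61, sigma_rep=0.0, beta_inter=0.0, **kwargs):
    d = m.generate_library(n_snps=n_snps, seed=seed)
    truth = m.make_truth(d, sigma_rep=sigma_rep, beta_inter=beta_inter, **kwargs)
    c = m.simulate_counts(d, truth, seed=seed + 1)
    expr, _ = m.filter_table(m.compute_expression(c), d)
    return d, expr


class TestFitter:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Interior-optimum fits match MixedLM coefficients and variances."""
        from statsmodels.regression.mixed_linear_model import MixedLM
        d, expr = _expr_for(n_snps=3, seed=61, sigma_rep=0.2,
                            beta_allele=0.3, beta_inter=0.2)
        compared = 0
        for snp in d.snp_ids:
            y, X, g, _ = _snp_long_data(expr, d, snp)
            fit = _profile_fit(_SuffStats.build(y, X, g), method="reml")
            mlm = MixedLM(y, X, groups=g).fit(reml=True, method="lbfgs")
            if not np.isfinite(mlm.llf) or np.asarray(mlm.cov_re)[0, 0] < 1e-8:
                continue  # MixedLM degenerate at the boundary
            np.testing.assert_allclose(fit["beta"], mlm.fe_params, atol=1e-6)
            np.testing.assert_allclose(fit["se"], mlm.bse_fe, atol=1e-4)
            assert fit["sigma_rep"] == pytest.approx(
                np.sqrt(np.asarray(mlm.cov_re)[0, 0]), abs=1e-3)
            compared += 1
        assert compared >= 1

    def test_ml_loglik_agrees_with_statsmodels(self):
        from statsmodels.regression.mixed_linear_model import MixedLM
        d, expr = _expr_for(n_snps=2, seed=71, sigma_rep=0.25)
        for snp in d.snp_ids:
            y, X, g, _ = _snp_long_data(expr, d, snp)
            fit = _profile_fit(_SuffStats.build(y, X, g), method="ml")
            mlm = MixedLM(y, X, groups=g).fit(reml=False, method="lbfgs")
            if not np.isfinite(mlm.llf):
                continue
            assert fit["loglik_ml"] == pytest.approx(mlm.llf, abs=1e-3)

    def test_balanced_design_equals_ols_when_no_group_variance(self):
        import statsmodels.api as sm
        d, expr = _expr_for(n_snps=2, seed=63, sigma_rep=0.0)
        for snp in d.snp_ids:
            y, X, g, _ = _snp_long_data(expr, d, snp)
            fit = _profile_fit(_SuffStats.build(y, X, g), method="reml")
            ols = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit["beta"], ols.params, atol=1e-6)
            np.testing.assert_allclose(fit["se"], ols.bse, atol=1e-6)


class TestFitLMM:
    def test_measurement_filter_boundary(self):
        """95 of 240 measurements -> skipped; 96 -> fitted."""
        d, expr = _expr_for(n_snps=1, seed=65)
        bcs = list(d.barcode_map["barcode"])
        flat = [(s, b) for b in bcs for s in expr.values.index]  # 240 cells
        # spread kept cells across alleles and conditions
        order = np.random.default_rng(0).permutation(len(flat))
        flat = [flat[i] for i in order]
        for keep, ok in [(96, True), (95, False)]:
            mask = expr.mask.copy()
            mask.loc[:, :] = False
            for s, b in flat[:keep]:
                mask.loc[s, b] = True
            e2 = m.ExpressionTable(values=expr.values, mask=mask,
                                   sample_meta=expr.sample_meta,
                                   dna_counts=expr.dna_counts,
                                   rna_zero=expr.rna_zero)
            if ok:
                assert m.fit_lmm(e2, d, "snp00001").n_measurements == keep
            else:
                with pytest.raises(InsufficientDataError):
                    m.fit_lmm(e2, d, "snp00001")

    def test_interaction_recovery(self):
        """Planted beta_inter=0.6 recovered within 3 SE over seeds."""
        d = m.generate_library(n_snps=1, seed=67)
        est = []
        for seed in range(25):
            truth = m.make_truth(d, beta_inter=0.6, sigma_e=0.12,
                                 sigma_rep=0.05)
            c = m.simulate_counts(d, truth, seed=6000 + seed)
            expr, _ = m.filter_table(m.compute_expression(c), d)
            est.append(m.fit_lmm(expr, d, "snp00001").beta_inter)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.6) < 3 * se + 1e-3


class TestBasalFNull:
    def test_deterministic(self, small_design, null_expr):
        n1 = m.basal_F_null(null_expr, small_design, n_sims=200, seed=5)
        n2 = m.basal_F_null(null_expr, small_design, n_sims=200, seed=5)
        for k in n1:
            np.testing.assert_array_equal(n1[k].stats, n2[k].stats)

    def test_zero_sims_rejected(self, small_design, null_expr):
        with pytest.raises(InsufficientDataError):
            m.basal_F_null(null_expr, small_design, n_sims=0)

    def test_null_F_quantile_near_parametric(self):
        """Without barcode offsets, the allele-F null tracks F(1, df).

        The permutation null conditions on one realized basal set, so its
        quantile wobbles dataset to dataset; average a few datasets.
        """
        d = m.generate_library(n_snps=1, seed=81)
        q95s = []
        for seed in (82, 84, 86, 88):
            truth = m.make_truth(d, sigma_bc=0.0)
            c = m.simulate_counts(d, truth, seed=seed)
            expr, _ = m.filter_table(m.compute_expression(c), d)
            nulls = m.basal_F_null(expr, d, n_sims=1000, seed=seed + 1)
            q95s.append(np.percentile(nulls["allele"].stats, 95))
        ref = stats.f.ppf(0.95, 1, 236)  # 240 cells - 4 fixed coefficients
        assert np.mean(q95s) == pytest.approx(ref, rel=0.20)


class TestLMMEmpiricalP:
    def _result(self, Fa, Fd, Fi):
        return m.LMMResult("s", 0, 0, 0, 1, 1, 1, Fa, Fd, Fi, 0, 0.1, 240,
                           0.0, True)

    def _nulls(self, stats_):
        null = m.BasalNull("lmm_F", np.array(stats_, float), len(stats_), 10, 0)
        return {"allele": null, "drug": null, "inter": null}

    def test_enumerated_fixture(self):
        res = m.lmm_empirical_p(self._result(2.5, 2.5, 2.5),
                                self._nulls([1, 2, 3, 4]))
        assert res.p_emp_inter == pytest.approx((1 + 2) / 5)

    def test_zero_F_gives_one(self):
        res = m.lmm_empirical_p(self._result(0, 0, 0), self._nulls([1, 2, 3, 4]))
        assert res.p_emp_allele == 1.0

    def test_extreme_F_gives_minimum(self):
        res = m.lmm_empirical_p(self._result(99, 99, 99),
                                self._nulls(list(range(20))))
        assert res.p_emp_inter == pytest.approx(1 / 21)


class TestLRT:
    def test_constant_interaction_column_gives_p_one(self):
        d, expr = _expr_for(n_snps=1, seed=69)
        alt_bcs = d.barcode_map.query("allele == 'alt'")["barcode"]
        atra = expr.condition_samples("ATRA")
        mask = expr.mask.copy()
        mask.loc[atra, list(alt_bcs)] = False  # no (alt, ATRA) cells
        e2 = m.ExpressionTable(values=expr.values, mask=mask,
                               sample_meta=expr.sample_meta,
                               dna_counts=expr.dna_counts, rna_zero=expr.rna_zero)
        assert m.lrt_interaction(e2, d, "snp00001") == 1.0

    def test_null_calibration(self):
        """Under beta_inter=0 the LRT p-value is ~uniform across seeds."""
        d = m.generate_library(n_snps=1, n_basal=0, seed=73)
        ps = []
        for seed in range(150):
            truth = m.make_truth(d, sigma_rep=0.05)
            c = m.simulate_counts(d, truth, seed=7000 + seed)
            expr, _ = m.filter_table(m.compute_expression(c), d)
            ps.append(m.lrt_interaction(expr, d, "snp00001"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_at_large_interaction(self):
        d = m.generate_library(n_snps=1, n_basal=0, seed=75)
        hits = 0
        for seed in range(30):
            truth = m.make_truth(d, beta_inter=1.0, sigma_e=0.12)
            c = m.simulate_counts(d, truth, seed=7500 + seed)
            expr, _ = m.filter_table(m.compute_expression(c), d)
            if m.lrt_interaction(expr, d, "snp00001") < 0.001:
                hits += 1
        assert hits >= int(0.95 * 30)


def reference_category(pa, pi, vp, vq, vd, ad):
    """Independent restatement of the classification rules."""
    inter = pi < 0.05
    allele = pa < 0.05
    if inter and allele:
        if vp < 0.1 and vq < 0.1 and vd == ad and vd != 0:
            return "both"
        return "interaction_only"
    if inter:
        return "interaction_only"
    if allele:
        return "allele_only"
    return "none"


class TestClassify:
    @pytest.mark.parametrize("pa", [0.01, 0.049, 0.05, 0.2])
    @pytest.mark.parametrize("pi", [0.01, 0.049, 0.05, 0.2])
    @pytest.mark.parametrize("vp", [0.05, 0.099, 0.1, 0.5])
    @pytest.mark.parametrize("vq", [0.05, 0.1, 0.5])
    @pytest.mark.parametrize("dirs", [(1, 1), (1, -1), (-1, -1), (0, 0)])
    def test_exhaustive_grid(self, pa, pi, vp, vq, dirs):
        vd, ad = dirs
        got = m.classify_effects(pa, pi, vehicle_pemp=vp, atra_fdr=vq,
                                 vehicle_direction=vd, atra_direction=ad)
        assert got == reference_category(pa, pi, vp, vq, vd, ad)

    def test_fig_rule_example(self):
        assert m.classify_effects(0.01, 0.01, vehicle_pemp=0.05, atra_fdr=0.05,
                                  vehicle_direction=1, atra_direction=1) == "both"

    def test_opposite_directions_demote_to_interaction_only(self):
        assert m.classify_effects(0.01, 0.01, vehicle_pemp=0.05, atra_fdr=0.05,
                                  vehicle_direction=1,
                                  atra_direction=-1) == "interaction_only"

    def test_nothing_significant(self):
        assert m.classify_effects(0.5, 0.5) == "none"

    def test_missing_single_condition_rejected(self):
        with pytest.raises(InsufficientDataError):
            m.classify_effects(0.01, 0.01)

    def test_custom_thresholds(self):
        th = Thresholds(inter_pemp=0.2, allele_pemp=0.001)
        assert m.classify_effects(0.01, 0.1, thresholds=th) == "interaction_only"


class TestVarianceHomogeneity:
    def test_identical_replicates_zero_sd(self, small_design, null_expr):
        e = null_expr
        vals = e.values.copy()
        for cond in ("vehicle", "ATRA"):
            samp = e.condition_samples(cond)
            vals.loc[samp] = vals.loc[samp].iloc[0].to_numpy()
        e2 = m.ExpressionTable(values=vals, mask=e.mask, sample_meta=e.sample_meta,
                               dna_counts=e.dna_counts, rna_zero=e.rna_zero)
        out = m.variance_homogeneity(e2)
        assert out.loc[["vehicle", "ATRA"], "median_sd"].eq(0).all()

    def test_matched_conditions_close_medians(self, null_expr):
        out = m.variance_homogeneity(null_expr)
        assert out.loc["abs_difference", "median_sd"] < 0.005

    def test_single_replicate_rejected(self, null_expr):
        e = null_expr
        keep = [e.condition_samples("vehicle")[0]] + e.condition_samples("ATRA")
        with pytest.raises(InsufficientDataError):
            m.variance_homogeneity(e.subset_samples(keep))


class TestRunInteractionAnalysis:
    def test_end_to_end_categories(self, effect_design_truth, effect_expr):
        d, truth = effect_design_truth
        lmm, vehicle, atra, skipped = m.run_interaction_analysis(
            effect_expr, d, n_sims=1500, seed=77)
        assert not skipped
        byid = lmm.set_index("snp_id")
        # strong planted interactions are detected as interactions
        assert byid.loc["snp00004", "p_emp_inter"] < 0.05
        assert byid.loc["snp00004", "lrt_p"] < 0.051
        # strong pure allelic effect -> allele_only, never interaction
        assert byid.loc["snp00001", "category"] == "allele_only"
        assert byid.loc["snp00001", "p_emp_allele"] < 0.05
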
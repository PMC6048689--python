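"""Normalization, consistency filtering, moderated t and BH adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulseprot.differential import (
    FilterCriteria,
    VariancePrior,
    bh_adjust,
    call_changes,
    estimate_variance_prior,
    filter_consistent,
    moderated_test,
    normalize_log_ratios,
)
from pulseprot.errors import EstimationError, NormalizationError, ValidationError

from conftest import make_samples, quant_from_ratios


class TestNormalization:
    def test_median_centering(self):
        samples = make_samples(3)
        ratios = pd.DataFrame([[1.0], [2.0], [4.0]], index=["P0", "P1", "P2"])
        ratios = pd.concat([ratios] * 3, axis=1)
        rm = normalize_log_ratios(quant_from_ratios(ratios, samples))
        np.testing.assert_allclose(
            rm.values.iloc[:, 0].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_all_equal_ratios_normalize_to_zero(self):
        samples = make_samples(2)
        ratios = pd.DataFrame(1.7, index=[f"P{i}" for i in range(4)], columns=range(2))
        rm = normalize_log_ratios(quant_from_ratios(ratios, samples))
        np.testing.assert_allclose(rm.values.to_numpy(), 0.0, atol=1e-12)

    def test_per_sample_medians_zero(self, rng):
        samples = make_samples(4)
        ratios = pd.DataFrame(
            rng.lognormal(0.2, 0.6, (30, 4)), index=[f"P{i}" for i in range(30)]
        )
        ratios[rng.random((30, 4)) < 0.2] = np.nan
        rm = normalize_log_ratios(quant_from_ratios(ratios, samples))
        med = rm.values.median(axis=0, skipna=True)
        np.testing.assert_allclose(med.to_numpy(), 0.0, atol=1e-9)
        # offsets audit: adding them back recovers raw log2 ratios
        raw = np.log2(ratios.to_numpy())
        np.testing.assert_allclose(
            rm.values.add(rm.offsets, axis=1).to_numpy(), raw, atol=1e-12, equal_nan=True
        )

    def test_idempotent(self, rng):
        samples = make_samples(3)
        ratios = pd.DataFrame(
            rng.lognormal(0, 0.5, (20, 3)), index=[f"P{i}" for i in range(20)]
        )
        quant = quant_from_ratios(ratios, samples)
        once = normalize_log_ratios(quant).values
        # re-centering already centered values changes nothing
        again = once.sub(once.median(axis=0), axis=1)
        np.testing.assert_allclose(once.to_numpy(), again.to_numpy(), atol=1e-12, equal_nan=True)

    def test_low_ratio_count_excluded(self):
        samples = make_samples(2)
        ratios = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], index=["P0", "P1"])
        counts = pd.DataFrame([[1.0, 2.0], [2.0, 2.0]], index=["P0", "P1"])
        rm = normalize_log_ratios(quant_from_ratios(ratios, samples, counts=counts))
        assert math.isnan(rm.values.iloc[0, 0])
        assert not math.isnan(rm.values.iloc[0, 1])

    def test_empty_sample_named_in_error(self):
        samples = make_samples(2)
        ratios = pd.DataFrame([[1.0, np.nan], [2.0, np.nan]], index=["P0", "P1"])
        with pytest.raises(NormalizationError, match=samples[1].sample_id):
            normalize_log_ratios(quant_from_ratios(ratios, samples))


class TestFilterConsistent:
    def _ratio_matrix(self, table: pd.DataFrame):
        samples = make_samples(table.shape[1])
        quant = quant_from_ratios(2.0**table, samples)
        return normalize_log_ratios(quant), samples

    def test_forty_percent_quantified_not_consistent(self):
        # 2 of 5 replicates quantified: fails the strict >50% criterion
        row = [1.0, 1.0, np.nan, np.nan, np.nan]
        table = pd.DataFrame([row] + [[0.0] * 5] * 9, index=[f"P{i}" for i in range(10)])
        rm, _ = self._ratio_matrix(table)
        calls = filter_consistent(rm)
        assert not calls.loc["P0", "consistent"]
        assert calls.loc["P0", "frac_quantified"] == pytest.approx(0.4)

    def test_constant_half_log_ratio_consistent(self):
        table = pd.DataFrame(
            [[0.5, 0.5, 0.5]] + [[0.0] * 3] * 9, index=[f"P{i}" for i in range(10)]
        )
        rm, _ = self._ratio_matrix(table)
        calls = filter_consistent(rm)
        assert calls.loc["P0", "mean"] == pytest.approx(0.5)
        assert calls.loc["P0", "sd"] == pytest.approx(0.0)
        assert bool(calls.loc["P0", "consistent"])
        assert calls.loc["P0", "direction"] == "up"

    def test_single_replicate_sd_undefined(self):
        table = pd.DataFrame(
            [[0.9, np.nan, np.nan]] + [[0.0] * 3] * 9, index=[f"P{i}" for i in range(10)]
        )
        rm, _ = self._ratio_matrix(table)
        calls = filter_consistent(rm)
        assert not calls.loc["P0", "sd_defined"]
        assert not calls.loc["P0", "consistent"]

    def test_flags_match_bruteforce(self, rng):
        """Oracle: re-apply the three rules protein by protein."""
        n, r = 20, 5
        table = pd.DataFrame(
            rng.normal(0, 0.8, (n, r)), index=[f"P{i}" for i in range(n)]
        )
        table[rng.random((n, r)) < 0.3] = np.nan
        samples = make_samples(r)
        quant = quant_from_ratios(2.0**table, samples)
        rm = normalize_log_ratios(quant)
        calls = filter_consistent(rm)
        crit = FilterCriteria()
        for pid in table.index:
            vals = rm.values.loc[pid].dropna().to_numpy()
            if len(vals) >= 2:
                expected = (
                    (len(vals) / r > crit.min_fraction_quantified)
                    and (np.std(vals, ddof=1) <= crit.max_replicate_sd)
                    and (abs(np.mean(vals)) > crit.min_abs_avg_ratio)
                )
            else:
                expected = False
            assert bool(calls.loc[pid, "consistent"]) == expected, pid


class TestVariancePrior:
    def test_scaled_chisquare_recovery(self):
        d0_true, s0_true, g, d = 4.0, 0.25, 5000, 4
        rng = np.random.default_rng(7)
        true_var = d0_true * s0_true / rng.chisquare(d0_true, g)
        s2 = true_var * rng.chisquare(d, g) / d
        prior = estimate_variance_prior(s2, d)
        assert abs(prior.df_prior - d0_true) / d0_true < 0.25
        assert abs(prior.var_prior - s0_true) / s0_true < 0.10

    def test_identical_variances_take_infinite_branch(self):
        prior = estimate_variance_prior(np.full(50, 0.3), 4.0)
        assert math.isinf(prior.df_prior)
        assert prior.var_prior > 0

    def test_moment_equations_residual(self):
        """Plug-back oracle: the returned (d0, s0) solves both equations."""
        from scipy.special import digamma, polygamma

        rng = np.random.default_rng(13)
        true_var = 4 * 0.25 / rng.chisquare(4, 2000)
        s2 = true_var * rng.chisquare(4, 2000) / 4
        prior = estimate_variance_prior(s2, 4.0)
        d = np.full_like(s2, 4.0)
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        mean_resid = (
            e.mean() - (math.log(prior.var_prior) - digamma(prior.df_prior / 2) + math.log(prior.df_prior / 2))
        )
        var_resid = e.var(ddof=1) - (
            polygamma(1, d / 2).mean() + polygamma(1, prior.df_prior / 2)
        )
        assert abs(mean_resid) < 1e-8
        assert abs(var_resid) < 1e-8

    def test_too_few_proteins_rejected(self):
        with pytest.raises(EstimationError):
            estimate_variance_prior(np.full(5, 0.3), 4.0)


class TestModeratedTest:
    def test_d0_zero_is_ordinary_t(self, rng):
        X = pd.DataFrame(rng.normal(0.2, 0.5, (30, 5)))
        st_mod = moderated_test(X, prior=VariancePrior(0.0, 1.0))
        t_ref, p_ref = stats.ttest_1samp(X, 0.0, axis=1)
        np.testing.assert_allclose(st_mod["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(st_mod["p"], p_ref, rtol=1e-12)

    def test_all_zero_ratios(self):
        X = pd.DataFrame(np.zeros((12, 4)))
        res = moderated_test(X, prior=VariancePrior(4.0, 0.1))
        assert (res["t"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_shrinkage_bound(self, rng):
        """Posterior variance lies between the sample and prior variances."""
        X = pd.DataFrame(rng.normal(0, 0.7, (100, 4)))
        prior = VariancePrior(3.0, 0.5)
        res = moderated_test(X, prior=prior)
        lo = np.minimum(res["var"], prior.var_prior)
        hi = np.maximum(res["var"], prior.var_prior)
        assert ((res["var_post"] >= lo - 1e-12) & (res["var_post"] <= hi + 1e-12)).all()

    def test_infinite_prior_limit(self, rng):
        X = pd.DataFrame(rng.normal(0, 0.5, (40, 5)))
        res = moderated_test(X, prior=VariancePrior(math.inf, 0.25))
        expected_t = X.mean(axis=1) * np.sqrt(5) / 0.5
        np.testing.assert_allclose(res["t"], expected_t, rtol=1e-12)
        np.testing.assert_allclose(res["p"], 2 * stats.norm.sf(np.abs(expected_t)), rtol=1e-12)

    def test_untested_proteins_flagged_not_dropped(self):
        X = pd.DataFrame(
            [[0.5, 0.6, 0.7], [0.5, np.nan, np.nan]], index=["P0", "P1"]
        )
        res = moderated_test(X, prior=VariancePrior(2.0, 0.2))
        assert res.loc["P1", "tested"] == False  # noqa: E712
        assert math.isnan(res.loc["P1", "p"])
        assert "P1" in res.index

    def test_matches_limma_ebayes_on_frozen_fixture(self):
        """Cross-check against limma::eBayes on a 40-protein fixture.

        Expected values were computed once with R/Bioconductor limma 3.58.1
        (lmFit with an intercept-only design followed by eBayes) on exactly
        this generated matrix, and frozen.
        """
        rng = np.random.default_rng(123)
        X = rng.normal(0.1, 0.4, size=(40, 4)) * np.sqrt(rng.chisquare(4, size=(40, 1)) / 4)
        X[rng.random(X.shape) < 0.1] = np.nan
        res = moderated_test(pd.DataFrame(X))
        assert res.attrs["df_prior"] == pytest.approx(3.829750523, rel=1e-8)
        assert res.attrs["var_prior"] == pytest.approx(0.07622775645, rel=1e-8)
        expected_t = [0.3876773295, 1.318921502, -0.8689057511, 1.723833112, 0.523871527]
        expected_p = [0.7120129086, 0.2296949743, 0.4143873821, 0.1294651783, 0.6196765466]
        np.testing.assert_allclose(res["t"].iloc[:5], expected_t, rtol=1e-8)
        np.testing.assert_allclose(res["p"].iloc[:5], expected_p, rtol=1e-8)


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @staticmethod
    def brute_force_bh(p):
        p = list(p)
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        for rank_pos, i in enumerate(order):
            candidates = [
                p[j] * m / (pos + 1)
                for pos, j in enumerate(order)
                if pos >= rank_pos
            ]
            q[i] = min(1.0, min(candidates))
        return q

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            p = np.clip(p, 1e-12, 1.0)
            np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = np.clip(rng.random(200), 1e-12, 1.0)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_p(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_ties_get_equal_q(self):
        q = bh_adjust([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [float("nan")]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)


class TestFullPipeline:
    def test_significant_implies_consistent(self, rng):
        from pulseprot.simulate import SimConfig, simulate_pulse_experiment

        quant, _ = simulate_pulse_experiment(
            SimConfig(n_proteins=500, n_replicates=5, pi_up=0.1, delta=1.0, seed=6)
        )
        calls = list(call_changes(quant).values())[0]
        assert (calls["significant"] <= calls["consistent"]).all()
        # direction defined wherever the mean is non-zero
        has_dir = calls["direction"].notna()
        assert (calls.loc[has_dir, "mean"] != 0).all()
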
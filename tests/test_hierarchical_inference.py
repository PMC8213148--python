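import copy
import math

import numpy as np
import pytest

import delaydisc as dd
from delaydisc.hierarchical_inference import (
    FitResult,
    MCMCConfig,
    PriorSpec,
    compute_dic,
    fit_hierarchical,
    gelman_rubin,
    hdi,
)


class TestGelmanRubin:
    def test_identical_chains_give_rhat_at_most_one(self, rng):
        x = rng.standard_normal(1000)
        r = gelman_rubin(np.stack([x, x]))
        assert r == pytest.approx(math.sqrt(999 / 1000), abs=1e-12)
        assert r <= 1.0005

    def test_offset_chains_flagged(self, rng):
        x = rng.standard_normal(500)
        r = gelman_rubin(np.stack([x, x + 100 * x.std()]))
        assert r > 1.01

    def test_same_distribution_chains_converge(self, rng):
        chains = rng.standard_normal((2, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_matches_hand_formula(self, rng):
        chains = rng.standard_normal((3, 200)) + np.array([[0.0], [0.1], [-0.2]])
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected)

    def test_constant_chains_return_one_by_convention(self):
        assert gelman_rubin(np.full((2, 50), 3.14)) == 1.0

    def test_rejects_single_chain_and_short_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((2, 5)))


class TestHdi:
    def test_constant_samples_zero_width(self):
        lo, hi = hdi(np.full(500, 2.0), 0.95)
        assert lo == hi == 2.0

    def test_uniform_width_matches_mass(self, rng):
        lo, hi = hdi(rng.random(100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_nesting(self, rng):
        x = rng.standard_normal(20_000)
        lo85, hi85 = hdi(x, 0.85)
        lo95, hi95 = hdi(x, 0.95)
        assert lo95 <= lo85 and hi85 <= hi95

    def test_agrees_with_independent_reference(self, rng):
        arviz = pytest.importorskip("arviz")
        x = rng.gamma(3.0, 1.0, size=50_000)
        lo, hi = hdi(x, 0.9)
        ref = arviz.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.03)
        assert hi == pytest.approx(ref[1], abs=0.03)

    def test_rejects_bad_mass(self, rng):
        with pytest.raises(ValueError):
            hdi(rng.random(500), 1.0)


class TestDic:
    def _one_subject_data(self):
        trials = [dd.Trial(2.0, 0.0, 5.0, d, c) for d, c in
                  [(10.0, 1), (20.0, 1), (30.0, 0), (60.0, 0)]]
        return dd.ChoiceDataset(
            subjects=[dd.SubjectRecord("s1", "g", trials)],
            delay_unit="seconds", currency_unit="cents")

    def _fit_from_trace(self, data, lk_draws, br_draws, family="hyperbolic"):
        """Assemble a FitResult from hand-listed subject-level draws."""
        n = len(lk_draws)
        samples = {
            "log_k": np.array(lk_draws).reshape(1, n, 1),
            "beta_raw": np.array(br_draws).reshape(1, n, 1),
        }
        dev = np.array([
            -2.0 * dd.dataset_loglik(data.subjects[0].trials,
                                     dd.SubjectParams(a, b), family)
            for a, b in zip(lk_draws, br_draws)]).reshape(1, n)
        return FitResult(samples=samples, subject_ids=["s1"], group_labels=["g"],
                         rhat={}, deviance=dev, family=family, grouping="pooled",
                         dic=math.nan, pd_eff=math.nan, converged=True,
                         data_fingerprint="")

    def test_degenerate_posterior_pd_zero(self):
        data = self._one_subject_data()
        fit = self._fit_from_trace(data, [-3.0] * 5, [0.5] * 5)
        dic, pd_eff = compute_dic(fit, data)
        assert pd_eff == pytest.approx(0.0, abs=1e-9)
        d_hat = -2.0 * dd.dataset_loglik(data.subjects[0].trials,
                                         dd.SubjectParams(-3.0, 0.5), "hyperbolic")
        assert dic == pytest.approx(d_hat)

    def test_three_sample_trace_matches_direct_arithmetic(self):
        data = self._one_subject_data()
        lk, br = [-3.5, -3.0, -2.5], [0.2, 0.5, 0.8]
        fit = self._fit_from_trace(data, lk, br)
        dic, pd_eff = compute_dic(fit, data)
        devs = [-2.0 * dd.dataset_loglik(data.subjects[0].trials,
                                         dd.SubjectParams(a, b), "hyperbolic")
                for a, b in zip(lk, br)]
        d_bar = float(np.mean(devs))
        d_hat = -2.0 * dd.dataset_loglik(data.subjects[0].trials,
                                         dd.SubjectParams(-3.0, 0.5), "hyperbolic")
        assert pd_eff == pytest.approx(d_bar - d_hat)
        assert dic == pytest.approx(2 * d_bar - d_hat)

    def test_dic_invariant_to_subject_ordering(self, small_fit,
                                               small_adolescent_cohort):
        perm = np.arange(len(small_fit.subject_ids))[::-1]
        shuffled = copy.deepcopy(small_fit)
        for name in ("log_k", "beta_raw"):
            shuffled.samples[name] = shuffled.samples[name][:, :, perm]
        shuffled.subject_ids = [small_fit.subject_ids[i] for i in perm]
        data_perm = dd.ChoiceDataset(
            subjects=[small_adolescent_cohort.subjects[i] for i in perm],
            delay_unit="seconds", currency_unit="cents")
        dic_a, _ = compute_dic(small_fit, small_adolescent_cohort)
        dic_b, _ = compute_dic(shuffled, data_perm)
        assert dic_a == pytest.approx(dic_b)


class TestFitHierarchical:
    def test_deterministic_given_seed(self, small_adolescent_cohort, quick_mcmc):
        f1 = fit_hierarchical(small_adolescent_cohort, "hyperbolic", cfg=quick_mcmc)
        f2 = fit_hierarchical(small_adolescent_cohort, "hyperbolic", cfg=quick_mcmc)
        for name in f1.samples:
            assert np.array_equal(f1.samples[name], f2.samples[name])
        assert f1.dic == f2.dic

    def test_rhat_recorded_for_every_parameter(self, small_fit,
                                               small_adolescent_cohort):
        n_sub = small_adolescent_cohort.n_subjects
        assert len(small_fit.rhat) == 2 * n_sub + 4 * 2

    def test_nonconvergence_flags_not_raises(self, small_adolescent_cohort, caplog):
        cfg = MCMCConfig(n_chains=2, n_iter=120, n_burnin=20, base_seed=0)
        with caplog.at_level("WARNING"):
            fit = fit_hierarchical(small_adolescent_cohort, "hyperbolic", cfg=cfg)
        if not fit.converged:  # 100 draws: essentially always flagged
            assert any("not converged" in r.message for r in caplog.records)

    def test_pooled_grouping_single_hyper_set(self, small_adolescent_cohort,
                                              quick_mcmc):
        fit = fit_hierarchical(small_adolescent_cohort, "hyperbolic",
                               cfg=quick_mcmc, grouping="pooled")
        assert fit.group_labels == ["all"]
        assert fit.samples["mu_log_k"].shape[2] == 1

    def test_group_mean_recovery_within_hdi(self, small_adolescent_cohort):
        """With 6+6 subjects the 95% HDI for each group's mean log k should
        cover the generating value (a coarse single-cohort recovery check)."""
        cfg = MCMCConfig(n_chains=2, n_iter=3000, n_burnin=1200, base_seed=5)
        fit = fit_hierarchical(small_adolescent_cohort, "hyperbolic", cfg=cfg)
        truth = small_adolescent_cohort.ground_truth
        for g in fit.group_labels:
            mu_true = truth.loc[truth.group == g, "true_mu_log_k"].iloc[0]
            lo, hi = hdi(fit.hyper_draws("mu_log_k", g), 0.95)
            assert lo <= mu_true <= hi

    def test_partial_pooling_shrinks_extreme_subject(self, adolescent_hypers):
        """A subject with an extreme response pattern should land between its
        individual MLE and the group mean (shrinkage signature). Subjects
        whose likelihood has no interior maximum (e.g. all-LL responders, for
        whom the MLE diverges) are excluded from the oracle."""
        spec = dd.CohortSpec(8, "adolescent_grid", {"g": adolescent_hypers},
                             seed=4242)
        data = dd.simulate_cohort(spec)
        cfg = MCMCConfig(n_chains=2, n_iter=2500, n_burnin=1000, base_seed=9)
        fit = fit_hierarchical(data, "hyperbolic", cfg=cfg, grouping="pooled")
        post = fit.subject_posterior_mean()
        group_mean = float(fit.samples["mu_log_k"].mean())

        lk_grid = np.linspace(-10.0, 1.0, 221)
        br_grid = np.linspace(-3.0, 4.0, 71)

        def grid_mle_log_k(trials):
            ll = np.array([[dd.dataset_loglik(trials, dd.SubjectParams(a, b),
                                              "hyperbolic")
                            for b in br_grid] for a in lk_grid])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            if i in (0, len(lk_grid) - 1) or j in (0, len(br_grid) - 1):
                return None  # no interior maximum: MLE degenerate
            # require a peaked profile in log_k: a flat plateau (e.g. all
            # subjective values saturated) leaves the MLE unidentified
            profile = ll.max(axis=1)
            if profile[0] > profile[i] - 2.0 or profile[-1] > profile[i] - 2.0:
                return None
            return lk_grid[i]

        mles = {s.subject_id: grid_mle_log_k(s.trials) for s in data.subjects}
        interior = {sid: m for sid, m in mles.items() if m is not None}
        assert interior, "expected at least one subject with an interior MLE"
        extreme = max(interior, key=lambda sid: abs(interior[sid] - group_mean))
        lo, hi = sorted((interior[extreme], group_mean))
        assert lo - 0.1 <= post[extreme].log_k <= hi + 0.1

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            PriorSpec(mu_log_k_scale=-1.0)
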
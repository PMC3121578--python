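"""Mixture-based copy-number calling: EM fits, BIC selection, posteriors,
batch pooling, goodness of fit and quality scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scipy.stats import kstest, norm

import cnvlatent as cl
from cnvlatent.calling import _quantile_init

from conftest import one_hot_cnv


def three_class_signal(rng, n=3000, sd=0.4, w=(0.25, 0.5, 0.25)):
    copy = rng.choice(3, size=n, p=w)
    return rng.normal(copy.astype(float), sd), copy


def reference_em(x, mu, sd, w, n_updates):
    """Independent, deliberately plain EM implementation (the oracle),
    run for a fixed number of update steps from the given start."""
    for _ in range(n_updates):
        dens = w[None, :] * norm.pdf(x[:, None], mu[None, :], sd[None, :])
        r = dens / dens.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0)
        w = nk / x.size
        mu = (r * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((r * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
    order = np.argsort(mu)
    return mu[order], sd[order], w[order]


class TestGaussianMixtureFit:
    def test_single_component_identity(self, rng):
        x = rng.normal(1.0, 0.1, size=500)
        fit = cl.fit_gaussian_mixture(x, n_components=1)
        assert fit.weights[0] == 1.0
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-8)
        assert fit.sds[0] == pytest.approx(x.std(), rel=1e-6)
        assert fit.converged

    def test_matches_independent_em_oracle_from_same_start(self, rng):
        x, _ = three_class_signal(rng)
        fit = cl.fit_gaussian_mixture(x, n_components=3)
        assert fit.converged
        mu0, sd0, w0 = _quantile_init(x, np.ones_like(x), 3)
        # our loop evaluates the log-likelihood n_iter times and applies
        # n_iter - 1 parameter updates before the convergence break
        mu, sd, w = reference_em(x, mu0.copy(), sd0.copy(), w0.copy(), fit.n_iter - 1)
        assert fit.means == pytest.approx(mu, abs=1e-8)
        assert fit.sds == pytest.approx(sd, abs=1e-8)
        assert fit.weights == pytest.approx(w, abs=1e-8)

    def test_parameter_recovery_is_unbiased(self):
        # Monte-Carlo check: replicate-averaged estimates sit within
        # 3 * (replicate SD / sqrt(R)) of the generating values.
        R = 15
        est = []
        for r in range(R):
            rng = np.random.default_rng(1000 + r)
            x, _ = three_class_signal(rng)
            f = cl.fit_gaussian_mixture(x, n_components=3)
            est.append(np.concatenate([f.means, f.sds, f.weights]))
        est = np.asarray(est)
        truth = np.array([0, 1, 2, 0.4, 0.4, 0.4, 0.25, 0.5, 0.25])
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(R)
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * np.maximum(mc_se, 1e-3))

    def test_identical_intensities_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            cl.fit_gaussian_mixture(np.ones(50))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            cl.fit_gaussian_mixture(np.arange(5, dtype=float))

    def test_binned_method_close_to_raw(self, rng):
        # the binned (mixdist-like) flavour works on histogram counts, so it
        # agrees with the raw-data fit up to the binning coarseness
        x, _ = three_class_signal(rng, n=4000, sd=0.25)
        raw = cl.fit_gaussian_mixture(x, n_components=3, mix_method="em_raw")
        binned = cl.fit_gaussian_mixture(x, n_components=3, mix_method="em_binned")
        assert binned.means == pytest.approx(raw.means, abs=0.1)
        assert binned.weights == pytest.approx(raw.weights, abs=0.05)

    def test_threshold_zero_creates_point_mass(self, rng):
        x = np.concatenate([np.full(60, 0.001), rng.normal(0.25, 0.05, 240),
                            rng.normal(0.45, 0.05, 300)])
        fit = cl.fit_gaussian_mixture(x, n_components=2, threshold_zero=0.01)
        assert fit.has_zero_mass
        assert fit.means[0] == 0.0 and fit.sds[0] == 0.0
        assert fit.weights[0] == pytest.approx(60 / 600)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert fit.n_components == 3
        assert fit.n_used == 540


class TestModelSelection:
    def test_single_tight_gaussian_selects_one(self, rng):
        x = rng.normal(0.0, 0.05, size=400)
        assert cl.select_num_components(x, max_components=4) == 1

    def test_well_separated_three_components(self, rng):
        x, _ = three_class_signal(rng, n=1000, sd=0.1)
        assert cl.select_num_components(x, max_components=5) == 3

    def test_zero_class_counts_toward_total(self, rng):
        x = np.concatenate([np.full(80, 0.0), rng.normal(0.25, 0.04, 260),
                            rng.normal(0.45, 0.04, 310)])
        k = cl.select_num_components(x, threshold_zero=0.01, max_components=4)
        assert k == 3

    def test_bic_formula(self, rng):
        x = rng.normal(0.0, 1.0, size=200)
        fit = cl.fit_gaussian_mixture(x, n_components=2)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 5 * np.log(200), abs=1e-9)


class TestPooledPrevalences:
    def test_hand_computed_weighted_mean(self):
        pooled = cl.pool_prevalences([(0.5, 0.5), (0.25, 0.75)], [100, 300])
        assert pooled == pytest.approx([0.3125, 0.6875], abs=1e-15)

    def test_single_batch_identity(self):
        assert cl.pool_prevalences([(0.2, 0.8)], [57]) == pytest.approx([0.2, 0.8])

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError, match="length"):
            cl.pool_prevalences([(0.5, 0.5), (0.2, 0.3, 0.5)], [10, 10])

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=4),
        st.integers(10, 500),
        st.integers(10, 500),
    )
    def test_exact_weighted_mean_property(self, raw, n1, n2):
        w1 = np.array(raw) / np.sum(raw)
        w2 = w1[::-1].copy()
        pooled = cl.pool_prevalences([w1, w2], [n1, n2])
        brute = (n1 * w1 + n2 * w2) / (n1 + n2)
        assert pooled == pytest.approx(brute, abs=1e-15)
        assert pooled.sum() == pytest.approx(1.0, abs=1e-12)


class TestBatchedMixture:
    def test_identical_batches_pool_to_common_weights(self, rng):
        x, _ = three_class_signal(rng, n=2000, sd=0.15)
        batch = np.repeat(["a", "b"], 1000)
        sig = cl.SignalData(intensity=x, batch=batch)
        bf = cl.fit_batched_mixture(sig, n_components=3)
        for f in bf.per_batch.values():
            assert bf.pooled_weights == pytest.approx(f.weights, abs=0.05)

    def test_shifted_batches_recover_shared_prevalences(self):
        rng = np.random.default_rng(5)
        n = 1500
        c1 = rng.choice(3, n, p=[0.25, 0.5, 0.25])
        c2 = rng.choice(3, n, p=[0.25, 0.5, 0.25])
        x1 = rng.normal(c1.astype(float), 0.15)
        x2 = rng.normal(c2.astype(float) + 0.3, 0.15)  # batch shift
        sig = cl.SignalData(
            intensity=np.concatenate([x1, x2]),
            batch=np.repeat(["p1", "p2"], n),
        )
        bf = cl.fit_batched_mixture(sig, n_components=3)
        assert bf.pooled_weights == pytest.approx([0.25, 0.5, 0.25], abs=0.04)
        shift = bf.per_batch["p2"].means - bf.per_batch["p1"].means
        assert shift == pytest.approx([0.3, 0.3, 0.3], abs=0.06)

    def test_single_batch_reduces_to_plain_fit(self, rng):
        x, _ = three_class_signal(rng, n=1200, sd=0.1)
        sig = cl.SignalData(intensity=x, batch=np.repeat("only", 1200))
        bf = cl.fit_batched_mixture(sig, n_components=3)
        plain = cl.fit_gaussian_mixture(x, n_components=3)
        assert bf.per_batch["only"].means == pytest.approx(plain.means, abs=1e-6)
        assert bf.pooled_weights == pytest.approx(plain.weights, abs=1e-6)

    def test_small_batch_raises_naming_batch(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 1, 8)])
        sig = cl.SignalData(intensity=x, batch=np.array(["big"] * 200 + ["tiny"] * 8))
        with pytest.raises(ValueError, match="tiny"):
            cl.fit_batched_mixture(sig, n_components=2)


class TestPosteriorMatrix:
    def test_far_separated_component_centre(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 200), rng.normal(10, 0.1, 200), [10.0]])
        fit = cl.fit_gaussian_mixture(x, n_components=2)
        cnv = cl.posterior_matrix(fit, x)
        assert cnv.prob[-1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_symmetry(self):
        fit = cl.MixtureFit(
            means=[0.0, 2.0], sds=[0.5, 0.5], weights=[0.5, 0.5],
            loglik=0.0, bic=0.0, n_used=10, converged=True,
        )
        cnv = cl.posterior_matrix(fit, np.array([1.0]))
        assert cnv.prob[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_direct_density_ratio_oracle(self, rng):
        x, _ = three_class_signal(rng, n=300, sd=0.3)
        fit = cl.fit_gaussian_mixture(x, n_components=3)
        y = x[:20]
        cnv = cl.posterior_matrix(fit, y)
        num = fit.weights[None, :] * norm.pdf(y[:, None], fit.means[None, :], fit.sds[None, :])
        expected = num / num.sum(axis=1, keepdims=True)
        assert cnv.prob == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one_and_threshold_rows_certain(self, rng):
        x = np.concatenate([np.zeros(50), rng.normal(0.3, 0.05, 300),
                            rng.normal(0.6, 0.05, 250)])
        fit = cl.fit_gaussian_mixture(x, n_components=2, threshold_zero=0.01)
        cnv = cl.posterior_matrix(fit, x)
        assert np.allclose(cnv.prob.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(cnv.prob[:50, 0] == 1.0)
        assert list(cnv.copies) == [0, 1, 2]

    def test_default_labels_without_zero_class(self, rng):
        x, _ = three_class_signal(rng, n=600, sd=0.1)
        cnv = cl.posterior_matrix(cl.fit_gaussian_mixture(x, n_components=3), x)
        assert list(cnv.copies) == [1, 2, 3]

    def test_batched_posteriors_use_batch_parameters(self):
        rng = np.random.default_rng(11)
        n = 800
        c = rng.choice(2, 2 * n, p=[0.5, 0.5])
        shift = np.repeat([0.0, 0.5], n)
        x = rng.normal(c.astype(float) + shift, 0.1)
        sig = cl.SignalData(intensity=x, batch=np.repeat(["a", "b"], n))
        bf = cl.fit_batched_mixture(sig, n_components=2)
        cnv = cl.posterior_matrix(bf, sig)
        # a signal of 0.5 is ambiguous in neither batch once the shift is known
        hard = cnv.best_guess()
        acc = (hard == cnv.copies[c]).mean()
        assert acc > 0.98


class TestCutpointsAndExternal:
    def test_basic_interval_assignment(self):
        cnv = cl.call_from_cutpoints(np.array([0.2]), cutpoints=[0.5], copies=[0, 1])
        assert cnv.prob[0] == pytest.approx([1.0, 0.0])

    def test_value_at_cutpoint_goes_up(self):
        cnv = cl.call_from_cutpoints(np.array([0.5, 0.49999]), cutpoints=[0.5], copies=[0, 1])
        assert cnv.prob[0, 1] == 1.0
        assert cnv.prob[1, 0] == 1.0

    def test_counts_match_brute_force(self, rng):
        y = rng.uniform(0, 3, size=100)
        cnv = cl.call_from_cutpoints(y, cutpoints=[1.0, 2.0])
        counts = cnv.prob.sum(axis=0)
        brute = [np.sum(y < 1), np.sum((y >= 1) & (y < 2)), np.sum(y >= 2)]
        assert counts == pytest.approx(brute)

    def test_non_ascending_cutpoints(self):
        with pytest.raises(ValueError, match="ascending"):
            cl.call_from_cutpoints(np.arange(5.0), cutpoints=[2.0, 1.0])

    def test_external_identity_rows_unchanged(self):
        p = np.eye(3)[[0, 1, 2, 1]]
        cnv = cl.cnv_from_probabilities(p)
        assert np.array_equal(cnv.prob, p)
        assert cnv.source == "external"

    def test_external_renormalisation(self):
        cnv = cl.cnv_from_probabilities(np.array([[2.0, 2.0]]))
        assert cnv.prob[0] == pytest.approx([0.5, 0.5])

    def test_external_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            cl.cnv_from_probabilities(np.array([[0.5, -0.1]]))
        with pytest.raises(ValueError, match="zero total"):
            cl.cnv_from_probabilities(np.array([[1.0, 0.0], [0.0, 0.0]]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_renormalisation_idempotent(self, seed):
        r = np.random.default_rng(seed)
        p = r.random((5, 3)) + 1e-3
        once = cl.cnv_from_probabilities(p)
        twice = cl.cnv_from_probabilities(once.prob)
        assert twice.prob == pytest.approx(once.prob, abs=1e-14)


class TestRelabel:
    def test_probabilities_bit_identical(self):
        p = np.array([[0.2, 0.3, 0.5], [0.6, 0.3, 0.1]])
        cnv = cl.cnv_from_probabilities(p, copies=[1, 2, 3])
        out = cl.relabel_copies(cnv, [0, 1, 2])
        assert np.array_equal(out.prob, cnv.prob)
        assert list(out.copies) == [0, 1, 2]

    def test_idempotence(self):
        cnv = cl.cnv_from_probabilities(np.array([[0.5, 0.5]]), copies=[1, 2])
        a = cl.relabel_copies(cl.relabel_copies(cnv, [5, 6]), [0, 1])
        b = cl.relabel_copies(cnv, [0, 1])
        assert np.array_equal(a.prob, b.prob) and np.array_equal(a.copies, b.copies)

    def test_wrong_length(self):
        cnv = cl.cnv_from_probabilities(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            cl.relabel_copies(cnv, [0, 1, 2])

    def test_additive_trend_invariant_under_label_shift(self, rng):
        n = 800
        copy = rng.choice(3, n, p=[0.25, 0.5, 0.25])
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.4 * copy)))).astype(float)
        base = one_hot_cnv(copy)
        shifted = cl.relabel_copies(base, [2, 3, 4])
        f0 = cl.fit_latent_model(y, base, model="additive")
        f1 = cl.fit_latent_model(y, shifted, model="additive")
        assert f1.params[1] == pytest.approx(f0.params[1], abs=1e-7)
        assert f1.params[0] == pytest.approx(f0.params[0] - 2 * f0.params[1], abs=1e-6)


class TestGoodnessOfFit:
    def test_statistic_nonnegative_and_reasonable_under_h0(self, rng):
        x, _ = three_class_signal(rng, n=1500, sd=0.12)
        fit = cl.fit_gaussian_mixture(x, n_components=3)
        gof = cl.goodness_of_fit(fit, x)
        assert gof.statistic >= 0
        assert 0 <= gof.pvalue <= 1

    def test_pvalues_uniform_under_h0_known_parameters(self):
        # data drawn exactly from the evaluated mixture: the Pearson p-value
        # is uniform (KS on 200 replicate p-values not rejected at 1%)
        truth = cl.MixtureFit(
            means=[0.0, 1.5], sds=[0.3, 0.3], weights=[0.6, 0.4],
            loglik=0.0, bic=0.0, n_used=600, converged=True,
        )
        pvals = []
        for r in range(200):
            rng = np.random.default_rng(3000 + r)
            c = rng.random(600) < 0.6
            x = np.where(c, rng.normal(0, 0.3, 600), rng.normal(1.5, 0.3, 600))
            pvals.append(cl.goodness_of_fit(truth, x, params_estimated=False).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_pvalues_roughly_calibrated_after_estimation(self):
        # with EM-estimated parameters the df correction is approximate
        # (the statistic is stochastically a little larger than the
        # chi-square reference); require no gross excess of small p-values
        pvals = []
        for r in range(200):
            rng = np.random.default_rng(3000 + r)
            c = rng.random(600) < 0.6
            x = np.where(c, rng.normal(0, 0.3, 600), rng.normal(1.5, 0.3, 600))
            fit = cl.fit_gaussian_mixture(x, n_components=2)
            pvals.append(cl.goodness_of_fit(fit, x).pvalue)
        pvals = np.asarray(pvals)
        assert np.mean(pvals < 0.05) < 0.15
        assert 0.2 < np.median(pvals) < 0.8

    def test_misspecification_detected(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 1000), rng.normal(2, 0.3, 1000)])
        fit = cl.fit_gaussian_mixture(x, n_components=1)
        assert cl.goodness_of_fit(fit, x).pvalue < 0.001


class TestQualityScore:
    def test_certain_calls_class_score_one(self):
        cnv = one_hot_cnv([0, 1, 2, 1, 0])
        assert cl.quality_score(cnv, "class").value == 1.0

    def test_cnvtools_hand_value(self):
        fit = cl.MixtureFit(
            means=[0.0, 3.0], sds=[0.5, 0.5], weights=[0.5, 0.5],
            loglik=0.0, bic=0.0, n_used=10, converged=True,
        )
        cnv = cl.posterior_matrix(fit, np.array([0.1, 2.9]))
        assert cl.quality_score(cnv, "cnvtools").value == pytest.approx(6.0)

    def test_unit_spacing_common_sigma_gives_inverse_sigma(self):
        fit = cl.MixtureFit(
            means=[0.0, 1.0, 2.0], sds=[0.25] * 3, weights=[0.25, 0.5, 0.25],
            loglik=0.0, bic=0.0, n_used=10, converged=True,
        )
        cnv = cl.posterior_matrix(fit, np.array([0.5]))
        assert cl.quality_score(cnv, "cnvtools").value == pytest.approx(4.0)

    def test_separation_limit_class_score_to_one(self, rng):
        scores = []
        for gap in (0.5, 2.0, 8.0):
            c = rng.choice(2, 500)
            x = rng.normal(c * gap, 0.3)
            fit = cl.fit_gaussian_mixture(x, n_components=2)
            scores.append(cl.quality_score(cl.posterior_matrix(fit, x), "class").value)
        assert scores[0] < scores[1] < scores[2]
        assert scores[2] > 0.999

    def test_cnvtools_requires_mixture_backing(self):
        cnv = cl.cnv_from_probabilities(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="mixture"):
            cl.quality_score(cnv, "cnvtools")


def test_model_results_front_end(rng):
    x, _ = three_class_signal(rng, n=900, sd=0.1)
    res = cl.GaussianSignalMixture(x).fit(n_components="auto", max_components=4)
    assert res.converged
    cnv = res.posterior()
    assert cnv.n == 900 and cnv.n_classes == 3
    assert "Gaussian mixture" in res.summary()
    assert res.quality_score("class").value > 0.99
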
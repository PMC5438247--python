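import numpy as np
import pytest
from scipy import integrate, optimize, stats

from odorcode.latmix import (MixtureConstraints, bootstrap_cis,
                             constrained_from_fits, fit_mixture,
                             latency_samples, mixture_loglik,
                             sample_truncated_mixture, select_k_by_bic,
                             two_phase_summary)
from odorcode.latmix import _trunc_logpdf

# the generator's default three-phase latency structure (lowest conc)
W3 = (0.40, 0.45, 0.15)
MU3 = (0.07, 0.206, 0.35)
SG3 = (0.018, 0.030, 0.06)


def _sample3(rng, n=400):
    return sample_truncated_mixture(rng, W3, MU3, SG3, n)


def _truncnorm_moment_estimate(x, bounds=(0.0, 0.5)):
    """Closed-form-style oracle for k=1: solve the truncated-normal
    moment equations for (mu, sigma) from the sample mean/variance."""
    a, b = bounds
    m, v = x.mean(), x.var()

    def eqs(theta):
        mu, ls = theta
        s = np.exp(ls)
        al, be = (a - mu) / s, (b - mu) / s
        z = stats.norm.cdf(be) - stats.norm.cdf(al)
        pa, pb = stats.norm.pdf(al), stats.norm.pdf(be)
        mean = mu + s * (pa - pb) / z
        var = s * s * (1 + (al * pa - be * pb) / z - ((pa - pb) / z) ** 2)
        return [mean - m, var - v]

    sol = optimize.root(eqs, [m, np.log(x.std())])
    return sol.x[0], float(np.exp(sol.x[1]))


class TestTruncatedDensity:
    @pytest.mark.parametrize("mu,sigma", [(0.1, 0.02), (0.45, 0.1),
                                          (-0.05, 0.08), (0.25, 0.3)])
    def test_component_density_integrates_to_one(self, mu, sigma):
        val, _ = integrate.quad(
            lambda x: np.exp(_trunc_logpdf(np.array([x]), mu, sigma,
                                           (0.0, 0.5)))[0], 0.0, 0.5,
            limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_density_zero_outside_bounds(self):
        lp = _trunc_logpdf(np.array([-0.01, 0.51]), 0.2, 0.05, (0.0, 0.5))
        assert np.all(np.isneginf(lp))


class TestFitMixture:
    def test_k1_matches_sample_moments_far_from_bounds(self, rng):
        x = rng.normal(0.25, 0.02, 5000)
        fit = fit_mixture(x, 1, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-4)
        assert fit.sigmas[0] == pytest.approx(x.std(), abs=1e-4)

    def test_k1_matches_moment_estimator_oracle(self, rng):
        """Near the truncation bound the MLE agrees with the
        moment-equation estimator on large samples."""
        raw = rng.normal(0.04, 0.03, 40000)
        x = raw[(raw >= 0) & (raw <= 0.5)]
        fit = fit_mixture(x, 1, seed=0)
        mu_o, sg_o = _truncnorm_moment_estimate(x)
        assert fit.means[0] == pytest.approx(mu_o, abs=2e-3)
        assert fit.sigmas[0] == pytest.approx(sg_o, abs=2e-3)

    def test_two_component_recovery(self, rng):
        x = sample_truncated_mixture(rng, [0.5, 0.5], [0.08, 0.25],
                                     [0.015, 0.04], 2000)
        fit = fit_mixture(x, 2, seed=1)
        assert fit.converged
        assert fit.means == pytest.approx([0.08, 0.25], abs=0.01)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_loglik_nesting(self, rng):
        x = _sample3(rng, 500)
        f1 = fit_mixture(x, 1, seed=2)
        f2 = fit_mixture(x, 2, seed=2)
        assert f2.log_likelihood > f1.log_likelihood

    def test_em_loglik_monotone(self, rng):
        x = _sample3(rng, 300)
        fit = fit_mixture(x, 3, seed=3, keep_trace=True)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_components_sorted_by_mean(self, rng):
        fit = fit_mixture(_sample3(rng, 400), 3, seed=4)
        assert np.all(np.diff(fit.means) > 0)

    def test_matches_direct_likelihood_maximization(self, rng):
        """Independent oracle: direct numerical maximization of the full
        mixture likelihood does not beat the EM fit."""
        x = sample_truncated_mixture(rng, [0.5, 0.5], [0.08, 0.25],
                                     [0.015, 0.04], 800)
        fit = fit_mixture(x, 2, seed=5)

        def negll(theta):
            w = 1 / (1 + np.exp(-theta[0]))
            return -mixture_loglik(x, np.array([w, 1 - w]), theta[1:3],
                                   np.exp(theta[3:5]))

        w0 = fit.weights[0]
        theta0 = np.r_[np.log(w0 / (1 - w0)), fit.means,
                       np.log(fit.sigmas)]
        res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8,
                                         "fatol": 1e-10})
        assert fit.log_likelihood >= -res.fun - 1e-3

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture(rng.uniform(0, 0.5, 10), 3)

    def test_out_of_bounds_latencies_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            fit_mixture(np.array([0.1] * 20 + [0.6]), 1)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mixture(np.full(50, 0.2), 1)


class TestConstraints:
    def test_frozen_parameters_unchanged(self, rng):
        x = _sample3(rng, 400)
        cons = MixtureConstraints(weights=np.array(W3),
                                  means={2: 0.35}, sigmas={2: 0.06})
        fit = fit_mixture(x, 3, constraints=cons, seed=6)
        assert fit.converged
        np.testing.assert_allclose(fit.weights, np.array(W3) / sum(W3))
        assert fit.means[2] == 0.35
        assert fit.sigmas[2] == 0.06

    def test_free_parameter_count(self):
        cons = MixtureConstraints(weights=np.ones(3) / 3,
                                  means={2: 0.3}, sigmas={2: 0.05})
        assert cons.n_free(3) == 4  # mu1, mu2, sigma1, sigma2
        assert MixtureConstraints().n_free(3) == 8  # 3k - 1

    def test_constrained_from_fits_averages(self, rng):
        fits = [fit_mixture(_sample3(rng, 300), 3, seed=s)
                for s in (7, 8)]
        cons = constrained_from_fits(fits)
        np.testing.assert_allclose(
            cons.weights, np.mean([f.weights for f in fits], axis=0))
        assert cons.means[2] == pytest.approx(
            np.mean([f.means[2] for f in fits]))


class TestModelSelection:
    def test_unimodal_sample_selects_k1(self, rng):
        x = np.clip(rng.normal(0.25, 0.03, 400), 0.001, 0.499)
        best, table = select_k_by_bic(x, range(1, 4), seed=0)
        assert best == 1

    def test_bimodal_sample_selects_k2(self, rng):
        x = sample_truncated_mixture(rng, [0.5, 0.5], [0.07, 0.3],
                                     [0.015, 0.03], 600)
        best, _ = select_k_by_bic(x, range(1, 4), seed=1)
        assert best == 2

    def test_loglik_nondecreasing_in_k(self, rng):
        x = _sample3(rng, 400)
        _, table = select_k_by_bic(x, range(1, 5), seed=2)
        ll = table["log_likelihood"].to_numpy()
        assert np.all(np.diff(ll) > -1e-6)


class TestBootstrap:
    def test_point_estimate_inside_its_own_ci(self, rng):
        x = _sample3(rng, 400)
        fit = fit_mixture(x, 3, seed=9)
        ci = bootstrap_cis(x, 3, n_boot=60, seed=10, point_fit=fit)
        inside = [(ci.lo["means"][j] <= fit.means[j] <= ci.hi["means"][j])
                  for j in range(3)]
        assert sum(inside) >= 2

    def test_ci_width_shrinks_with_sample_size(self, rng):
        """Quadrupling n shrinks the mu2 CI width roughly sqrt(2)-fold
        per doubling (allow generous slack)."""
        widths = {}
        for n in (250, 1000):
            x = _sample3(rng, n)
            fit = fit_mixture(x, 3, seed=11)
            ci = bootstrap_cis(x, 3, n_boot=60, seed=12, point_fit=fit)
            widths[n] = ci.hi["means"][1] - ci.lo["means"][1]
        assert widths[1000] < widths[250]

    def test_degenerate_bootstrap_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.full(60, 0.2), 2)


@pytest.fixture(scope="module")
def samples_by_conc():
    rng = np.random.default_rng(42)
    late = {0.0003: 0.206, 0.001: 0.183, 0.003: 0.159, 0.01: 0.136}
    return {c: sample_truncated_mixture(
        rng, W3, (MU3[0], mu2, MU3[2]), SG3, 450)
        for c, mu2 in late.items()}


class TestTwoPhaseSummary:

    def test_mu2_decreases_mu1_stable(self, samples_by_conc):
        out = two_phase_summary(samples_by_conc, k=3, constrained=True,
                                seed=0)
        mu2 = out["mu2"].to_numpy()
        assert np.all(np.diff(mu2) < 0)
        assert np.ptp(out["mu1"].to_numpy()) < 0.020

    def test_identical_samples_give_flat_curves(self, rng):
        x = _sample3(rng, 400)
        out = two_phase_summary({c: x for c in (0.001, 0.003, 0.01)},
                                k=3, constrained=True, seed=1)
        assert np.ptp(out["mu1"]) < 5e-3
        assert np.ptp(out["mu2"]) < 5e-3

    def test_constrained_refit_narrows_mu2_ci(self, samples_by_conc):
        """Freezing the mixing proportions and the slow component
        reduces bootstrap uncertainty on the second component mean."""
        x = samples_by_conc[0.0003]
        fit = fit_mixture(x, 3, seed=2)
        ci_free = bootstrap_cis(x, 3, n_boot=80, seed=3, point_fit=fit)
        cons = constrained_from_fits([fit])
        fit_c = fit_mixture(x, 3, constraints=cons, seed=4,
                            init=(fit.weights, fit.means, fit.sigmas))
        ci_cons = bootstrap_cis(x, 3, constraints=cons, n_boot=80, seed=5,
                                point_fit=fit_c)
        w_free = ci_free.hi["means"][1] - ci_free.lo["means"][1]
        w_cons = ci_cons.hi["means"][1] - ci_cons.lo["means"][1]
        assert w_cons <= w_free


def test_latency_sample_inclusion_rule(small_stats, small_dataset):
    """Only cell-odor pairs with a defined KDF peak at every
    concentration contribute, and they contribute at every
    concentration."""
    samples = latency_samples(small_stats, small_dataset.units)
    pcx = {c: len(v) for (r, c), v in samples.items() if r == "PCx"}
    assert len(set(pcx.values())) == 1  # same pair count per concentration
    for (_, c), v in samples.items():
        assert np.all((v >= 0) & (v <= 0.5))
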
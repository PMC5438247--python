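"""Mixtures of truncated Gaussians for peak-latency distributions.

Peak latencies of odor responses live on a bounded window (0-0.5 s after
inhalation onset), so each mixture component is a normal density
renormalized on that support.  Fitting is maximum likelihood via EM:

* E-step: posterior component responsibilities under the truncated
  densities;
* M-step: mixing proportions from responsibilities; each component's
  (mu, sigma) by maximizing its weighted truncated-normal log-likelihood,
  which depends on the data only through three sufficient statistics and
  is optimized numerically (L-BFGS with analytic gradients, warm-started
  at the current parameters, so the observed log-likelihood never
  decreases).

Initialization uses k-means cluster assignments; the whole procedure is
restarted several times and the best converged fit kept.  Component count
is selected by BIC, confidence intervals by the percentile bootstrap, and
any subset of parameters can be frozen for constrained refits (e.g.
holding the mixing proportions and the slowest component fixed while the
first two component means are re-estimated per concentration).

Components are reported in increasing-mean order; matching components
across bootstrap resamples or concentrations by that ordering is a known
limitation when components overlap.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp

DEFAULT_BOUNDS = (0.0, 0.5)
SIGMA_FLOOR = 1e-3
_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@dataclasses.dataclass
class MixtureConstraints:
    """Frozen parameters for constrained refits.

    ``weights`` fixes the full mixing-proportion vector; ``means`` and
    ``sigmas`` map component index -> frozen value.
    """

    weights: np.ndarray | None = None
    means: Mapping[int, float] = dataclasses.field(default_factory=dict)
    sigmas: Mapping[int, float] = dataclasses.field(default_factory=dict)

    def n_free(self, k: int) -> int:
        q = 0 if self.weights is not None else k - 1
        q += sum(1 for j in range(k) if j not in self.means)
        q += sum(1 for j in range(k) if j not in self.sigmas)
        return q


@dataclasses.dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    bounds: tuple
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    n_restarts_used: int
    n: int
    loglik_trace: np.ndarray | None = None

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        dens = np.zeros_like(x)
        for p, m, s in zip(self.weights, self.means, self.sigmas):
            dens += p * np.exp(_trunc_logpdf(x, m, s, self.bounds))
        return dens


def _trunc_logpdf(x, mu, sigma, bounds):
    a, b = bounds
    alpha = (a - mu) / sigma
    beta = (b - mu) / sigma
    logz = _log_z(alpha, beta)
    out = (-0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)
           - _LOG_SQRT_2PI - logz)
    return np.where((x >= a) & (x <= b), out, -np.inf)


def _log_z(alpha, beta):
    """log(Phi(beta) - Phi(alpha)), stable in the tails."""
    la, lb = log_ndtr(alpha), log_ndtr(beta)
    with np.errstate(divide="ignore"):
        return lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))


def _component_logpdf_matrix(x, means, sigmas, bounds):
    return np.column_stack([_trunc_logpdf(x, m, s, bounds)
                            for m, s in zip(means, sigmas)])


def mixture_loglik(x, weights, means, sigmas, bounds=DEFAULT_BOUNDS) -> float:
    lp = _component_logpdf_matrix(x, means, sigmas, bounds)
    return float(logsumexp(lp + np.log(weights)[None, :], axis=1).sum())


def _mstep_objective(theta, W, Sx, Sxx, bounds):
    """Negative weighted truncated-normal log-likelihood and gradient in
    theta = (mu, log sigma), written in sufficient statistics."""
    mu, ls = theta
    sigma = np.exp(ls)
    a, b = bounds
    alpha = (a - mu) / sigma
    beta = (b - mu) / sigma
    logz = _log_z(alpha, beta)
    quad = Sxx - 2 * mu * Sx + mu * mu * W
    g = -W * ls - 0.5 * quad / sigma ** 2 - W * logz
    # gradient
    z = np.exp(logz)
    z = max(z, 1e-300)
    pa = np.exp(-0.5 * alpha * alpha) / np.sqrt(2 * np.pi)
    pb = np.exp(-0.5 * beta * beta) / np.sqrt(2 * np.pi)
    dmu = (Sx - mu * W) / sigma ** 2 - W * (pa - pb) / (sigma * z)
    dls = -W + quad / sigma ** 2 - W * (alpha * pa - beta * pb) / z
    return -g, -np.array([dmu, dls])


def _optimize_component(W, Sx, Sxx, mu0, sigma0, bounds, fix_mu, fix_sigma,
                        sigma_floor):
    a, b = bounds
    span = b - a
    if fix_mu is not None and fix_sigma is not None:
        return fix_mu, fix_sigma
    theta0 = np.array([mu0 if fix_mu is None else fix_mu,
                       np.log(sigma0 if fix_sigma is None else fix_sigma)])
    lb = np.array([a - 0.5 * span, np.log(sigma_floor)])
    ub = np.array([b + 0.5 * span, np.log(2.0 * span)])
    if fix_mu is not None:
        lb[0] = ub[0] = fix_mu
    if fix_sigma is not None:
        lb[1] = ub[1] = np.log(fix_sigma)
    res = optimize.minimize(
        _mstep_objective, theta0, args=(W, Sx, Sxx, bounds),
        jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)), options={"maxiter": 60})
    f0, _ = _mstep_objective(theta0, W, Sx, Sxx, bounds)
    if not np.isfinite(res.fun) or res.fun > f0:
        return theta0[0], float(np.exp(theta0[1]))  # keep current: GEM-safe
    return float(res.x[0]), float(np.exp(res.x[1]))


def _em(x, weights, means, sigmas, constraints, bounds, max_iter, tol,
        sigma_floor):
    n = len(x)
    trace = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _component_logpdf_matrix(x, means, sigmas, bounds) \
            + np.log(weights)[None, :]
        ll_vec = logsumexp(lp, axis=1)
        ll = float(ll_vec.sum())
        trace.append(ll)
        if np.isfinite(ll) and ll - ll_old < tol * n and it > 1:
            converged = ll >= ll_old - 1e-9
            break
        ll_old = ll
        r = np.exp(lp - ll_vec[:, None])
        W = r.sum(axis=0)
        if constraints.weights is None:
            weights = np.maximum(W / n, 1e-12)
            weights = weights / weights.sum()
        Sx = r.T @ x
        Sxx = r.T @ (x * x)
        for j in range(len(means)):
            if W[j] < 1e-8:
                continue
            mu0 = Sx[j] / W[j]
            var0 = max(Sxx[j] / W[j] - mu0 ** 2, sigma_floor ** 2)
            means[j], sigmas[j] = _optimize_component(
                W[j], Sx[j], Sxx[j],
                means[j] if np.isfinite(means[j]) else mu0,
                max(sigmas[j], sigma_floor), bounds,
                constraints.means.get(j), constraints.sigmas.get(j),
                sigma_floor)
            sigmas[j] = max(sigmas[j], sigma_floor)
    ll = mixture_loglik(x, weights, means, sigmas, bounds)
    return weights, means, sigmas, ll, converged, it, np.asarray(trace)


def _kmeans_init(rng, x, k):
    """k-means cluster assignments on the latencies (1-D)."""
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=1,
                random_state=int(rng.integers(2 ** 31 - 1)))
    lab = km.fit_predict(x[:, None])
    weights = np.array([(lab == j).mean() for j in range(k)])
    means = np.array([x[lab == j].mean() if (lab == j).any() else x.mean()
                      for j in range(k)])
    sigmas = np.array([x[lab == j].std() if (lab == j).sum() > 1 else x.std()
                       for j in range(k)])
    sigmas = np.maximum(sigmas, 5 * SIGMA_FLOOR)
    weights = np.maximum(weights, 1e-3)
    return weights / weights.sum(), means, sigmas


def fit_mixture(latencies, k: int,
                constraints: MixtureConstraints | None = None,
                bounds: tuple = DEFAULT_BOUNDS, max_iter: int = 8000,
                n_restarts: int = 5, tol: float = 1e-7,
                seed: int | None = None,
                init: tuple | None = None,
                keep_trace: bool = False) -> MixtureFit:
    """Maximum-likelihood k-component truncated-Gaussian mixture fit.

    Each restart is initialized from k-means cluster assignments; the
    best converged restart (by log-likelihood) is returned.  Restarts
    whose smallest sigma collapses to the floor (1 ms) count as
    non-converged.  ``init = (weights, means, sigmas)`` warm-starts a
    single extra restart (used for bootstrap refits).  A fit with no
    converged restart is returned flagged, parameters NaN.

    Requires ``len(latencies) >= 5 * k`` and all latencies within the
    truncation bounds.
    """
    x = np.sort(np.asarray(latencies, float))
    constraints = constraints or MixtureConstraints()
    a, b = bounds
    if len(x) < 5 * k:
        raise ValueError(f"need at least {5 * k} latencies for k={k}")
    if x[0] < a or x[-1] > b:
        raise ValueError("latencies outside truncation bounds")
    if np.ptp(x) < SIGMA_FLOOR:
        raise ValueError("degenerate (zero-variance) latency sample")
    rng = np.random.default_rng(seed)

    starts = []
    if init is not None:
        starts.append(tuple(np.array(v, float) for v in init))
    for _ in range(n_restarts):
        starts.append(_kmeans_init(rng, x, k))

    best = None
    n_used = 0
    for w0, m0, s0 in starts:
        n_used += 1
        if constraints.weights is not None:
            w0 = np.asarray(constraints.weights, float)
            w0 = w0 / w0.sum()
        m0 = m0.copy()
        s0 = s0.copy()
        for j, v in constraints.means.items():
            m0[j] = v
        for j, v in constraints.sigmas.items():
            s0[j] = v
        w, m, s, ll, conv, it, trace = _em(
            x, w0.copy(), m0, s0, constraints, bounds, max_iter, tol,
            SIGMA_FLOOR)
        free_sigmas = [s[j] for j in range(k) if j not in constraints.sigmas]
        if free_sigmas and min(free_sigmas) <= SIGMA_FLOOR * 1.001:
            conv = False
        if conv and (best is None or ll > best[3]):
            best = (w, m, s, ll, it, trace)

    q = constraints.n_free(k)
    if best is None:
        nanarr = np.full(k, np.nan)
        return MixtureFit(k, nanarr, nanarr, nanarr, bounds, np.nan, np.nan,
                          False, max_iter, n_used, len(x))
    w, m, s, ll, it, trace = best
    if not constraints.means and not constraints.sigmas:
        order = np.argsort(m)
        w, m, s = w[order], m[order], s[order]
    bic = -2 * ll + q * np.log(len(x))
    return MixtureFit(k, w, m, s, bounds, ll, bic, True, it, n_used, len(x),
                      trace if keep_trace else None)


def select_k_by_bic(latencies, k_range: Sequence[int] = range(1, 6),
                    seed: int | None = None, **kwargs
                    ) -> tuple[int, pd.DataFrame]:
    """Fit each k and pick the lowest BIC among converged fits.

    BIC = -2 logL + q ln(n) with q = 3k - 1 free parameters for an
    unconstrained fit (truncation bounds are fixed, not estimated).
    Non-converging k values are skipped.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for k in k_range:
        try:
            fit = fit_mixture(latencies, k,
                              seed=int(rng.integers(2 ** 31 - 1)), **kwargs)
        except ValueError:
            continue
        rows.append({"k": k, "log_likelihood": fit.log_likelihood,
                     "bic": fit.bic, "converged": fit.converged})
    df = pd.DataFrame(rows)
    ok = df[df["converged"]]
    if len(ok) == 0:
        raise RuntimeError("no converged fit for any k")
    best_k = int(ok.loc[ok["bic"].idxmin(), "k"])
    return best_k, df


@dataclasses.dataclass
class BootstrapCI:
    """Percentile bootstrap intervals, components matched by mean order."""

    k: int
    lo: dict
    hi: dict
    estimates: dict
    n_boot: int
    n_converged: int


def bootstrap_cis(latencies, k: int,
                  constraints: MixtureConstraints | None = None,
                  n_boot: int = 1000, seed: int | None = None,
                  point_fit: MixtureFit | None = None,
                  n_restarts: int = 0, max_iter: int = 2000,
                  band: tuple = (2.5, 97.5), **kwargs) -> BootstrapCI:
    """Refit equally sized with-replacement resamples and take per-parameter
    percentile intervals.

    Resample fits warm-start at the point estimate (plus ``n_restarts``
    fresh k-means starts).  A warning-level note is attached when fewer
    than half the resamples converge.
    """
    x = np.asarray(latencies, float)
    rng = np.random.default_rng(seed)
    if point_fit is None:
        point_fit = fit_mixture(x, k, constraints=constraints,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                **kwargs)
    init = (point_fit.weights, point_fit.means, point_fit.sigmas) \
        if point_fit.converged else None
    samples = {"weights": [], "means": [], "sigmas": []}
    n_conv = 0
    for _ in range(n_boot):
        xb = rng.choice(x, len(x), replace=True)
        try:
            fit = fit_mixture(xb, k, constraints=constraints,
                              n_restarts=n_restarts, max_iter=max_iter,
                              seed=int(rng.integers(2 ** 31 - 1)),
                              init=init, **kwargs)
        except ValueError:
            continue
        if not fit.converged:
            continue
        n_conv += 1
        samples["weights"].append(fit.weights)
        samples["means"].append(fit.means)
        samples["sigmas"].append(fit.sigmas)
    if n_conv == 0:
        raise RuntimeError("no bootstrap resample converged")
    lo, hi, est = {}, {}, {}
    for name in samples:
        arr = np.vstack(samples[name])
        lo[name], hi[name] = np.percentile(arr, band, axis=0)
        est[name] = getattr(point_fit, name)
    ci = BootstrapCI(k, lo, hi, est, n_boot, n_conv)
    if n_conv < 0.5 * n_boot:
        import logging
        logging.getLogger(__name__).warning(
            "only %d/%d bootstrap fits converged", n_conv, n_boot)
    return ci


def constrained_from_fits(fits: Sequence[MixtureFit],
                          fixed_components: Sequence[int] = (2,)
                          ) -> MixtureConstraints:
    """Constraints for the standard two-phase protocol: mixing proportions
    for all components and all parameters of the listed (slowest)
    components held at the mean of the per-concentration estimates."""
    weights = np.mean([f.weights for f in fits], axis=0)
    means = {j: float(np.mean([f.means[j] for f in fits]))
             for j in fixed_components}
    sigmas = {j: float(np.mean([f.sigmas[j] for f in fits]))
              for j in fixed_components}
    return MixtureConstraints(weights=weights, means=means, sigmas=sigmas)


def two_phase_summary(samples_by_concentration: Mapping[float, np.ndarray],
                      k: int = 3, constrained: bool = True,
                      n_boot: int = 0, seed: int | None = None,
                      **kwargs) -> pd.DataFrame:
    """First- and second-component means versus concentration.

    Fits each concentration's latency sample with a k-component mixture;
    when ``constrained`` the fits are then redone holding the mixing
    proportions and the slowest component at the across-concentration
    mean of the unconstrained estimates, so that only the timing of the
    two principal phases is re-estimated per concentration.  With
    ``n_boot > 0`` percentile CIs for the component means are attached.
    """
    rng = np.random.default_rng(seed)
    concs = sorted(samples_by_concentration)
    fits = {}
    for c in concs:
        fits[c] = fit_mixture(samples_by_concentration[c], k,
                              seed=int(rng.integers(2 ** 31 - 1)), **kwargs)
    if any(not f.converged for f in fits.values()):
        bad = [c for c, f in fits.items() if not f.converged]
        raise RuntimeError(f"unconstrained fit did not converge at {bad}")
    constraints = None
    if constrained:
        constraints = constrained_from_fits(list(fits.values()))
        for c in concs:
            fits[c] = fit_mixture(samples_by_concentration[c], k,
                                  constraints=constraints,
                                  seed=int(rng.integers(2 ** 31 - 1)),
                                  init=(fits[c].weights, fits[c].means,
                                        fits[c].sigmas),
                                  **kwargs)
    rows = []
    for c in concs:
        f = fits[c]
        row = {"concentration": c, "mu1": f.means[0], "mu2": f.means[1],
               "sigma1": f.sigmas[0], "sigma2": f.sigmas[1],
               "converged": f.converged}
        if n_boot:
            ci = bootstrap_cis(samples_by_concentration[c], k,
                               constraints=constraints, n_boot=n_boot,
                               seed=int(rng.integers(2 ** 31 - 1)),
                               point_fit=f, **kwargs)
            row.update({"mu1_lo": ci.lo["means"][0],
                        "mu1_hi": ci.hi["means"][0],
                        "mu2_lo": ci.lo["means"][1],
                        "mu2_hi": ci.hi["means"][1]})
        rows.append(row)
    return pd.DataFrame(rows)


def sample_truncated_mixture(rng, weights, means, sigmas, n,
                             bounds=DEFAULT_BOUNDS) -> np.ndarray:
    """Draw latencies from a truncated-Gaussian mixture (rejection within
    each component); handy for simulations and tests."""
    weights = np.asarray(weights, float)
    comp = rng.choice(len(weights), n, p=weights / weights.sum())
    out = np.empty(n)
    a, b = bounds
    for j in range(len(weights)):
        m = comp == j
        need = int(m.sum())
        vals = np.empty(0)
        while len(vals) < need:
            draw = rng.normal(means[j], sigmas[j], max(2 * need, 16))
            vals = np.concatenate([vals, draw[(draw >= a) & (draw <= b)]])
        out[m] = vals[:need]
    return out


def latency_samples(stats_table: pd.DataFrame, units: pd.DataFrame,
                    concentrations: Sequence[float] | None = None
                    ) -> dict[tuple[str, float], np.ndarray]:
    """Pooled peak-latency samples per (region, concentration).

    Only concentration-series odorants contribute, and a cell-odor pair is
    included only when its trial-averaged KDF has a defined peak (inside
    the 0-0.5 s window) at every concentration.  Latencies are pooled
    across all units of a region before fitting.
    """
    df = stats_table.merge(units[["unit_id", "region"]], on="unit_id")
    series = [od for od, grp in df.groupby("odorant")
              if grp["concentration"].nunique() > 1]
    df = df[df["odorant"].isin(series)]
    if concentrations is None:
        concentrations = sorted(df["concentration"].unique())
    out: dict[tuple[str, float], list] = {}
    for (u, od), grp in df.groupby(["unit_id", "odorant"]):
        lat = grp.set_index("concentration")["peak_latency"]
        vals = [lat.get(c, np.nan) for c in concentrations]
        if not np.all(np.isfinite(vals)):
            continue
        region = grp["region"].iloc[0]
        for c, v in zip(concentrations, vals):
            out.setdefault((region, float(c)), []).append(float(v))
    return {key: np.asarray(v) for key, v in out.items()}
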
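"""One-dimensional Gaussian mixtures for synchronizer classification.

The population question — are there two kinds of synchronizers, or a
single continuum? — is answered by fitting Gaussian mixtures with 1,
2 and 3 components to the cohort's PLVs and choosing the component
count by the Akaike Information Criterion, AIC = 2p - 2 ln L with
p = 3k - 1 free parameters for k components (k weights minus the
sum-to-one constraint, k means, k variances).  When the two-component
model wins, each participant is assigned to the component with the
larger posterior responsibility; the higher-mean component defines the
"high synchronizer" group.

EM is implemented here directly (expectation of component membership,
then closed-form weight/mean/variance updates) rather than delegated,
so that initialization, the convergence rule and the collapse
diagnostics exactly match the procedure described in the docs.
Initialization is deterministic: component means start at evenly
spaced sample quantiles with equal weights and the pooled variance.
A component whose variance falls to the floor (1e-10 in squared-PLV
units, i.e. an SD of 1e-5 — far below any real between-participant
spread) has collapsed onto a point; the fit is then flagged
non-converged and model selection discards it, the same way a
three-component fit on strongly two-lobed data fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["MixtureFit", "Classification", "fit_gmm", "select_k_by_aic", "classify"]

VAR_FLOOR = 1e-10
DEFAULT_TOL = 1e-6


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture with its EM trace and AIC."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray  # (n, k), rows sum to 1
    loglik_trace: np.ndarray
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(self.variances)

    def summary(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "aic": self.aic,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": len(self.loglik_trace),
        }


@dataclass
class Classification:
    """High/low synchronizer labels from a two-component fit."""

    labels: np.ndarray  # "high" / "low" per participant
    posterior_high: np.ndarray
    boundary_plv: float

    @property
    def n_high(self) -> int:
        return int(np.sum(self.labels == "high"))

    @property
    def n_low(self) -> int:
        return int(np.sum(self.labels == "low"))


def _log_density(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
                 variances: np.ndarray) -> np.ndarray:
    """Per-observation log mixture components, shape (n, k)."""
    sds = np.sqrt(variances)
    return np.log(weights)[None, :] + norm.logpdf(x[:, None], means[None, :], sds[None, :])


def fit_gmm(plvs, k: int = 2, max_iter: int = 140, tol: float = DEFAULT_TOL,
            seed: int | None = None, n_init: int = 1) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    ``max_iter`` defaults to 140 iterations.  Convergence means the
    relative log-likelihood improvement fell below ``tol`` before the
    iteration budget ran out *and* no component collapsed onto the
    variance floor.  With ``n_init > 1`` and a ``seed``, additional
    randomized starts (means drawn from the data) are run and the best
    converged likelihood kept; the default single start is the
    deterministic quantile initialization, so repeated fits agree.
    """
    x = np.asarray(plvs, dtype=float).ravel()
    n = len(x)
    if k <= 0:
        raise ValueError("k must be positive")
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")

    starts = [_quantile_init(x, k)]
    if n_init > 1:
        rng = np.random.default_rng(seed)
        pooled = float(np.var(x)) or VAR_FLOOR
        for _ in range(n_init - 1):
            means = np.sort(rng.choice(x, size=k, replace=False))
            starts.append((np.full(k, 1.0 / k), means, np.full(k, pooled)))

    best: MixtureFit | None = None
    for w0, m0, v0 in starts:
        fit = _em(x, w0, m0, v0, max_iter=max_iter, tol=tol)
        if best is None:
            best = fit
        elif (fit.converged, fit.loglik) > (best.converged, best.loglik):
            best = fit
    assert best is not None
    return best


def _quantile_init(x: np.ndarray, k: int):
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    pooled = float(np.var(x))
    if pooled < VAR_FLOOR:
        pooled = VAR_FLOOR
    return np.full(k, 1.0 / k), means.astype(float), np.full(k, pooled)


def _em(x: np.ndarray, weights: np.ndarray, means: np.ndarray, variances: np.ndarray,
        max_iter: int, tol: float) -> MixtureFit:
    n, k = len(x), len(means)
    weights = weights.copy()
    means = means.copy()
    variances = variances.copy()
    trace: list[float] = []
    converged = False
    collapsed = False
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E step
        log_comp = _log_density(x, weights, means, variances)
        log_norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - log_norm[:, None])
        ll = float(np.sum(log_norm))
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(variances < VAR_FLOOR):
            variances = np.maximum(variances, VAR_FLOOR)
            collapsed = True
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
    # final E step so responsibilities/trace match the returned parameters
    log_comp = _log_density(x, weights, means, variances)
    log_norm = logsumexp(log_comp, axis=1)
    resp = np.exp(log_comp - log_norm[:, None])
    trace.append(float(np.sum(log_norm)))
    return MixtureFit(k=k, weights=weights, means=means, variances=variances,
                      responsibilities=resp, loglik_trace=np.asarray(trace),
                      converged=converged and not collapsed)


def select_k_by_aic(plvs, k_candidates=(1, 2, 3), max_iter: int = 140,
                    tol: float = DEFAULT_TOL, seed: int | None = None,
                    n_init: int = 1) -> MixtureFit:
    """Fit each candidate component count and return the lowest-AIC fit.

    Non-converged candidates (including collapsed components) are
    excluded from the comparison.  If no candidate converges, the data
    cannot be described by any of the requested models and an error is
    raised.
    """
    x = np.asarray(plvs, dtype=float).ravel()
    fits = [fit_gmm(x, k=k, max_iter=max_iter, tol=tol, seed=seed, n_init=n_init)
            for k in k_candidates if len(x) >= k]
    if not fits:
        raise ValueError("no feasible component count for this sample size")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise RuntimeError("no candidate mixture converged")
    return min(converged, key=lambda f: f.aic)


def classify(fit: MixtureFit, plvs) -> Classification:
    """Assign high/low labels from a two-component fit.

    Each participant goes to the component with the larger posterior
    responsibility at their PLV; the higher-mean component is "high".
    Exact posterior ties break toward "low" (a measure-zero event,
    resolved conservatively).  ``boundary_plv`` is the PLV between the
    two component means where the posteriors cross, when it exists.
    """
    if fit.k != 2:
        raise ValueError("classification requires a two-component fit")
    x = np.asarray(plvs, dtype=float).ravel()
    hi = int(np.argmax(fit.means))
    log_comp = _log_density(x, fit.weights, fit.means, fit.variances)
    log_norm = logsumexp(log_comp, axis=1)
    post = np.exp(log_comp - log_norm[:, None])
    p_high = post[:, hi]
    labels = np.where(p_high > 0.5, "high", "low")

    def log_odds(v: float) -> float:
        lc = _log_density(np.asarray([v]), fit.weights, fit.means, fit.variances)[0]
        return lc[hi] - lc[1 - hi]

    lo_mean, hi_mean = sorted(fit.means)
    try:
        boundary = float(brentq(log_odds, lo_mean, hi_mean))
    except ValueError:
        boundary = float("nan")  # posteriors do not cross between the means
    return Classification(labels=labels, posterior_high=p_high, boundary_plv=boundary)
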
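"""Model comparison and calibration diagnostics.

* DIC: mean posterior deviance plus the effective number of parameters
  p_D = mean D(eta) - D(mean eta);
* WAIC: -2 (lppd - p_WAIC) with the pointwise log predictive density
  and the pointwise posterior variance penalty;
* randomized PIT for counts: u = F(O-1) + v [F(O) - F(O-1)] with F the
  posterior-predictive CDF averaged over draws — uniform u indicates a
  calibrated predictive distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats as sps

from .mcmc import FitResult

__all__ = ["dic", "waic", "pit", "pit_histogram"]


def _pointwise_loglik(fit: FitResult) -> np.ndarray:
    """(S, n, T) pointwise Poisson log likelihoods over pooled draws."""
    eta = fit.pooled("eta")            # (S, n, T)
    mu = fit.E[None] * np.exp(eta)
    o = fit.O[None]
    return o * np.log(mu) - mu - special.gammaln(o + 1)


def _deviance(fit: FitResult, eta: np.ndarray) -> float:
    mu = fit.E * np.exp(eta)
    return -2.0 * float(np.sum(fit.O * np.log(mu) - mu
                               - special.gammaln(fit.O + 1)))


def dic(fit: FitResult) -> tuple[float, float]:
    """Deviance information criterion and effective parameters p_D."""
    eta = fit.pooled("eta")
    if eta.shape[0] < 2:
        raise ValueError("DIC needs at least 2 posterior draws")
    devs = np.array([_deviance(fit, e) for e in eta])
    dbar = float(devs.mean())
    dhat = _deviance(fit, eta.mean(axis=0))
    p_d = dbar - dhat
    return dbar + p_d, p_d


def waic(fit: FitResult) -> tuple[float, float]:
    """Watanabe-Akaike criterion and its effective-parameter penalty."""
    ll = _pointwise_loglik(fit)
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    lppd = float(special.logsumexp(ll, axis=0).sum()
                 - ll.shape[1] * ll.shape[2] * np.log(ll.shape[0]))
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), p_waic


def pit(fit: FitResult, seed: int, method: str = "loo") -> np.ndarray:
    """Randomized probability integral transform, one value per cell.

    ``method="loo"`` (default) computes the cross-validated PIT via
    CPO-style importance weighting: the leave-one-out predictive CDF is

        P(Y_i <= y | y_{-i}) = E[F(y|eta_i)/p(y_i|eta_i)]
                               / E[1/p(y_i|eta_i)]

    with expectations over the full posterior.  In-sample PIT
    (``method="posterior"``) is over-concentrated when the model has
    cell-level random effects, so only the cross-validated version is
    meaningful as a calibration check."""
    eta = fit.pooled("eta")
    mu = fit.E[None] * np.exp(eta)          # (S, n, T)
    o = fit.O
    f_at = sps.poisson.cdf(o[None], mu)
    f_below = sps.poisson.cdf(o[None] - 1, mu)
    if method == "loo":
        logp = o[None] * np.log(mu) - mu - special.gammaln(o[None] + 1)
        logw = -logp - special.logsumexp(-logp, axis=0, keepdims=True)
        w = np.exp(logw)
    elif method == "posterior":
        w = np.full(f_at.shape[:1] + (1, 1), 1.0 / f_at.shape[0])
    else:
        raise ValueError(f"unknown PIT method {method!r}")
    f_at = (w * f_at).sum(axis=0)
    f_below = (w * f_below).sum(axis=0)
    rng = np.random.default_rng(seed)
    v = rng.random(o.shape)
    return f_below + v * (f_at - f_below)


def pit_histogram(fit: FitResult, seed: int,
                  bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PIT values binned into equal-width bins on [0, 1]."""
    u = pit(fit, seed)
    counts, edges = np.histogram(u.ravel(), bins=bins, range=(0.0, 1.0))
    return counts, edges
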
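"""Hyperpriors for the spatiotemporal model family.

Families:

* ``loggamma(a, b)`` — a Gamma(shape a, rate b) prior on a precision
  (equivalently a log-gamma prior on the log precision);
* ``pc_prec(U, alpha)`` — penalized-complexity prior on a precision tau,
  shrinking toward infinite precision (zero variance); the induced prior
  on the standard deviation sigma = tau^{-1/2} is Exponential(lambda)
  with lambda = -ln(alpha)/U, so P(sigma > U) = alpha;
* ``pc_mix(U, alpha)`` — distance-based PC prior for the BYM2 mixing
  parameter omega in [0, 1], base model omega = 0 (pure iid);
* ``pc_cor0(U, alpha)`` — distance-based PC prior for an AR(1)
  correlation, base model rho = 0 (white noise), P(|rho| > U) = alpha;
* ``normal(mean, variance)`` / ``flat_normal`` — Gaussian priors, e.g.
  N(0, 1e6) for the intercept or N(0, 0.15) for the transformed AR(1)
  coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, interpolate, optimize, special

__all__ = ["PriorSpec", "pc_prec_logpdf", "pc_prec_tail_sd",
           "loggamma_logpdf", "normal_logpdf", "PCMixingPrior",
           "PCCor0Prior", "ar1_unit_eigenvalues"]

_FAMILIES = ("loggamma", "pc_prec", "pc_cor0", "pc_mix", "normal",
             "flat_normal")


@dataclass(frozen=True)
class PriorSpec:
    """Declarative prior: family plus its (a,b) / (U,alpha) / (mean,var)."""

    family: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        a, b = self.params
        if self.family == "loggamma" and (a <= 0 or b <= 0):
            raise ValueError("loggamma requires a, b > 0")
        if self.family in ("pc_prec", "pc_cor0", "pc_mix"):
            if a <= 0 or not (0 < b < 1):
                raise ValueError("PC priors require U > 0 and alpha in (0,1)")
        if self.family == "normal" and b <= 0:
            raise ValueError("normal prior requires positive variance")


def pc_prec_logpdf(tau, U: float, alpha: float):
    """Log density of the PC precision prior.

    pi(tau) = (lambda/2) tau^{-3/2} exp(-lambda tau^{-1/2}),
    lambda = -ln(alpha)/U.
    """
    lam = -np.log(alpha) / U
    if isinstance(tau, float):  # fast scalar path for the sampler
        if tau <= 0:
            return -np.inf
        return float(np.log(lam / 2) - 1.5 * np.log(tau)
                     - lam / np.sqrt(tau))
    tau = np.asarray(tau, dtype=float)
    out = np.where(tau > 0,
                   np.log(lam / 2) - 1.5 * np.log(np.maximum(tau, 1e-300))
                   - lam / np.sqrt(np.maximum(tau, 1e-300)),
                   -np.inf)
    return out if out.ndim else float(out)


def pc_prec_tail_sd(threshold: float, U: float, alpha: float) -> float:
    """P(sigma > threshold) under pc_prec(U, alpha), by quadrature.

    Integrates the implemented tau-density over
    {tau : tau^{-1/2} > threshold} = (0, threshold^{-2}).
    """
    upper = threshold ** -2
    val, _ = integrate.quad(lambda t: np.exp(pc_prec_logpdf(t, U, alpha)),
                            0.0, upper, limit=200)
    return float(val)


def loggamma_logpdf(tau, a: float, b: float):
    """Gamma(shape a, rate b) log density on a precision."""
    tau = np.asarray(tau, dtype=float)
    out = np.where(tau > 0,
                   a * np.log(b) - special.gammaln(a)
                   + (a - 1) * np.log(np.maximum(tau, 1e-300)) - b * tau,
                   -np.inf)
    return out if out.ndim else float(out)


def normal_logpdf(x, mean: float, variance: float):
    x = np.asarray(x, dtype=float)
    out = -0.5 * (np.log(2 * np.pi * variance) + (x - mean) ** 2 / variance)
    return out if out.ndim else float(out)


class PCMixingPrior:
    """PC prior for the BYM2 mixing parameter omega (structured share).

    The BYM2 joint (unit marginal precision) has covariance
    ``(1-omega) I + omega * Sigma*`` with Sigma* the scaled ICAR
    generalized inverse.  On the constraint-orthogonal subspace with
    eigenvalues gamma_i of Sigma*, the KLD to the base model omega = 0
    is ``0.5 sum_i [omega (gamma_i - 1) - ln(1 + omega (gamma_i - 1))]``
    and the distance is d(omega) = sqrt(2 KLD).  An exponential prior is
    placed on d, truncated at d(1) and renormalized; its rate lambda is
    solved numerically so that P(omega > U) = alpha exactly.
    """

    def __init__(self, eigenvalues: np.ndarray, U: float = 0.5,
                 alpha: float = 0.5, grid_size: int = 2001):
        gam = np.asarray(eigenvalues, dtype=float)
        gam = gam[gam > 1e-10]  # constraint-orthogonal subspace only
        if gam.size == 0:
            raise ValueError("no positive eigenvalues supplied")
        if not (0 < U < 1):
            raise ValueError("U must lie in (0, 1) for a mixing parameter")
        self.U, self.alpha = float(U), float(alpha)
        self._gam = gam
        omega = np.linspace(0.0, 1.0, grid_size)
        self._d_grid = np.array([self._distance(w) for w in omega])
        self._omega_grid = omega
        self._d_interp = interpolate.CubicSpline(omega, self._d_grid)
        # midpoint derivative grid for the fast scalar path
        self._mid_grid = 0.5 * (omega[1:] + omega[:-1])
        self._dd_grid = np.diff(self._d_grid) / np.diff(omega)
        d_u, d_1 = self._distance(U), self._d_grid[-1]

        def tail(lam: float) -> float:
            # P(d > d_u) under Exp(lam) truncated to [0, d_1]; lam may be
            # negative (density increasing in distance) when the target
            # tail mass exceeds what the uniform-in-distance limit gives
            if abs(lam) < 1e-12:
                return 1.0 - d_u / d_1 - alpha
            if lam > 0:
                val = (np.expm1(-lam * d_u) - np.expm1(-lam * d_1)) \
                    / (-np.expm1(-lam * d_1))
            else:  # overflow-safe form for negative rates
                val = np.expm1(lam * (d_1 - d_u)) / np.expm1(lam * d_1)
            return float(val) - alpha

        lo, hi = None, None
        prev_l, prev_v = -1e6, tail(-1e6)
        for lam in np.concatenate([-np.geomspace(1e6, 1e-8, 60), [0.0],
                                   np.geomspace(1e-8, 1e6, 60)]):
            v = tail(lam)
            if prev_v == 0 or prev_v * v < 0:
                lo, hi = prev_l, lam
                break
            prev_l, prev_v = lam, v
        if lo is None:
            raise RuntimeError("failed to bracket lambda for pc_mix")
        self.lam = float(optimize.brentq(tail, lo, hi, xtol=1e-14))
        if abs(self.lam) < 1e-10:
            self.lam = 1e-10  # uniform-in-distance limit
        # log of lam / (1 - exp(-lam d_1)); both factors share a sign
        self._log_const = float(np.log(abs(self.lam))
                                - np.log(abs(np.expm1(-self.lam * d_1))))

    def _distance(self, omega: float) -> float:
        t = omega * (self._gam - 1.0)
        kld2 = np.sum(t - np.log1p(t))
        return float(np.sqrt(max(kld2, 0.0)))

    def logpdf(self, omega):
        if isinstance(omega, float):  # fast scalar path for the sampler
            if not 0.0 <= omega <= 1.0:
                return -np.inf
            d = float(np.interp(omega, self._omega_grid, self._d_grid))
            dd = float(np.interp(omega, self._mid_grid, self._dd_grid))
            return self._log_const - self.lam * d + np.log(abs(dd))
        omega = np.asarray(omega, dtype=float)
        scalar = omega.ndim == 0
        omega = np.atleast_1d(omega)
        d = self._d_interp(omega)
        dd = self._d_interp(omega, 1)
        out = np.where((omega >= 0) & (omega <= 1),
                       self._log_const - self.lam * d
                       + np.log(np.abs(dd)),
                       -np.inf)
        return float(out[0]) if scalar else out

    def pdf(self, omega):
        return np.exp(self.logpdf(omega))

    def tail_mass(self, threshold: float) -> float:
        """P(omega > threshold) by quadrature of the implemented density."""
        val, _ = integrate.quad(self.pdf, threshold, 1.0, limit=200)
        return float(val)

    def total_mass(self) -> float:
        val, _ = integrate.quad(self.pdf, 0.0, 1.0, limit=200)
        return float(val)


class PCCor0Prior:
    """PC prior for an AR(1) correlation with base model rho = 0.

    For a unit-marginal-variance AR(1) of length T the KLD to white
    noise is ``-(T-1)/2 ln(1 - rho^2)``, so
    d(rho) = sqrt(-(T-1) ln(1 - rho^2)).  The exponential prior on d
    (rate solving P(|rho| > U) = alpha) is split symmetrically over the
    two sign branches; d(1) is infinite so the density integrates to 1
    on (-1, 1) without truncation.
    """

    def __init__(self, T: int, U: float, alpha: float):
        if T < 2:
            raise ValueError("need T >= 2")
        if not (0 < U < 1):
            raise ValueError("U must lie in (0, 1)")
        self.T, self.U, self.alpha = int(T), float(U), float(alpha)
        self.lam = -np.log(alpha) / self._distance(U)

    def _distance(self, rho: float) -> float:
        return float(np.sqrt(-(self.T - 1) * np.log1p(-rho * rho)))

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        scalar = rho.ndim == 0
        rho = np.atleast_1d(rho)
        out = np.full(rho.shape, -np.inf)
        ok = np.abs(rho) < 1
        r = np.abs(rho[ok])
        d = np.sqrt(-(self.T - 1) * np.log1p(-r * r))
        denom = np.where(d > 0, (1 - r * r) * d, 1.0)
        dd = np.where(r > 0, (self.T - 1) * r / denom,
                      np.sqrt(self.T - 1.0))
        out[ok] = np.log(self.lam / 2) - self.lam * d + np.log(dd)
        return float(out[0]) if scalar else out

    def tail_mass(self, threshold: float) -> float:
        """P(|rho| > threshold) = exp(-lambda d(threshold))."""
        return float(np.exp(-self.lam * self._distance(threshold)))


def ar1_unit_eigenvalues(T: int, rho: float) -> np.ndarray:
    """Eigenvalues of the unit-marginal-variance AR(1) precision."""
    from .effects import ar1_precision
    return np.linalg.eigvalsh(ar1_precision(T, rho))
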
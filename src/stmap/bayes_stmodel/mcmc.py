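"""Poisson spatiotemporal hierarchical model and its MCMC sampler.

Model family for a balanced areal panel of observed counts O_it with
expected counts E_it (offsets):

    O_it | eta_it ~ Poisson(E_it * exp(eta_it))
    eta_it = alpha + b_i + gamma_t + phi_t + delta_it

with b_i a spatial block (iid, Besag/ICAR, BYM, or BYM2), gamma_t a
structured temporal block (RW1/RW2/AR(1)/AR(2)), phi_t iid temporal
noise, and delta_it a Knorr-Held space-time interaction (types I-IV).
The BYM2 block is the reparameterized convolution

    b_i = (1/sqrt(tau_b)) * (sqrt(1-omega) v_i + sqrt(omega) u*_i)

with v iid standard normal, u* the scaled ICAR effect (geometric-mean
marginal variance 1) and omega the structured share.

Inference is Metropolis-within-Gibbs: latent Gaussian vectors are
updated by single-site random-walk Metropolis vectorized over colour
classes of their conditional-dependence graphs (sites within a colour
are conditionally independent, so simultaneous accept/reject is exact);
precisions with loggamma (Gamma) priors are updated by conjugate Gibbs;
PC-prior hyperparameters, the BYM2 mixing, and AR coefficients by
random-walk Metropolis on unconstrained scales.  Proposal steps adapt
during burn-in toward 20-50% acceptance.  Sum-to-zero constraints of
improper blocks are re-imposed by centering after every sweep, with the
removed means transferred to the free blocks that absorb them (the
intercept, and phi for the interaction's per-year means) so the
likelihood is untouched where possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ..geo_weights import RegionGraph
from .effects import (EffectBlock, ar1_precision, ar2_precision,
                      build_icar_precision, build_interaction,
                      build_temporal_block)
from .priors import (PCCor0Prior, PCMixingPrior, PriorSpec, loggamma_logpdf,
                     normal_logpdf, pc_prec_logpdf)

__all__ = ["ModelSpec", "FitResult", "STModel", "fit_mcmc",
           "poisson_loglik", "default_priors"]

logger = logging.getLogger(__name__)

SPATIAL_KINDS = ("none", "iid", "besag", "bym", "bym2")
TEMPORAL_KINDS = ("none", "rw1", "rw2", "ar1", "ar2")
INTERACTIONS = ("none", "typeI", "typeII", "typeIII", "typeIV")

RHAT_LIMIT = 1.05


def default_priors(spatial: str, temporal_structured: str, temporal_iid: str,
                   interaction: str) -> dict[str, PriorSpec]:
    """Default hyperprior assignment for a model configuration.

    Precisions of classic BYM blocks get the weakly informative
    loggamma(1, 0.0005); BYM2/PC-style blocks get pc_prec(U=1,
    alpha=0.01); the BYM2 mixing gets pc(U=0.5, alpha=0.5); the AR(1)
    coefficient gets N(0, 0.15) on the transformed scale; the intercept
    gets N(0, 1e6).
    """
    pri: dict[str, PriorSpec] = {"alpha": PriorSpec("normal", (0.0, 1e6))}
    if spatial == "iid":
        pri["tau_v"] = PriorSpec("loggamma", (1.0, 5e-4))
    elif spatial == "besag":
        pri["tau_u"] = PriorSpec("loggamma", (1.0, 5e-4))
    elif spatial == "bym":
        pri["tau_u"] = PriorSpec("loggamma", (1.0, 5e-4))
        pri["tau_v"] = PriorSpec("loggamma", (1.0, 5e-4))
    elif spatial == "bym2":
        pri["tau_b"] = PriorSpec("pc_prec", (1.0, 0.01))
        pri["omega"] = PriorSpec("pc_mix", (0.5, 0.5))
    if temporal_structured in ("rw1", "rw2"):
        pri["tau_gamma"] = PriorSpec("loggamma", (1.0, 5e-4))
    elif temporal_structured in ("ar1", "ar2"):
        pri["tau_gamma"] = PriorSpec("pc_prec", (1.0, 0.01))
        pri["rho"] = PriorSpec("normal", (0.0, 0.15))
    if temporal_iid == "iid":
        pri["tau_phi"] = PriorSpec("pc_prec", (1.0, 0.01))
    if interaction != "none":
        pri["tau_delta"] = PriorSpec("pc_prec", (1.0, 0.01))
    return pri


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model in the family."""

    spatial: str = "bym2"
    temporal_structured: str = "ar1"
    temporal_iid: str = "iid"
    interaction: str = "typeIV"
    priors: Mapping[str, PriorSpec] = dc_field(default_factory=dict)
    rho_literal_scale: bool = False  # N(mean, var) on rho itself, not logit-like
    # identifiability constraints on the interaction: in addition to the
    # structural null-space constraints, centre delta over cities within
    # each year AND over years within each city, so it is orthogonal to
    # the spatial and temporal main effects.  Without this, interactions
    # with a proper temporal factor (AR) are confounded with the spatial
    # field and the AR coefficient is not recoverable.
    identifiable_interaction: bool = True

    def __post_init__(self) -> None:
        if self.spatial not in SPATIAL_KINDS:
            raise ValueError(f"unknown spatial block {self.spatial!r}")
        if self.temporal_structured not in TEMPORAL_KINDS:
            raise ValueError(
                f"unknown temporal block {self.temporal_structured!r}")
        if self.temporal_iid not in ("none", "iid"):
            raise ValueError(f"unknown temporal iid {self.temporal_iid!r}")
        if self.interaction not in INTERACTIONS:
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.interaction != "none":
            if self.spatial not in ("besag", "bym", "bym2") \
                    or self.temporal_structured == "none":
                raise ValueError("interaction requires structured spatial "
                                 "and temporal blocks")
        merged = default_priors(self.spatial, self.temporal_structured,
                                self.temporal_iid, self.interaction)
        extra = set(self.priors) - set(merged)
        if extra:
            raise ValueError(f"priors given for absent parameters: "
                             f"{sorted(extra)}")
        merged.update(self.priors)
        object.__setattr__(self, "priors", merged)

    def label(self) -> str:
        parts = [self.spatial, self.temporal_structured, self.temporal_iid,
                 self.interaction]
        return "+".join(p for p in parts if p != "none") or "intercept"


def poisson_loglik(O: np.ndarray, E: np.ndarray, eta: np.ndarray) -> float:
    """Full Poisson log likelihood with offset, log mu = log E + eta."""
    mu = E * np.exp(eta)
    return float(np.sum(O * np.log(mu) - mu - special.gammaln(O + 1)))


def _gmrf_logdensity(x: np.ndarray, Q: np.ndarray, tau: float,
                     rank: int) -> float:
    """Log density of x ~ N(0, (tau Q)^-) up to the structure's gdet."""
    vals = np.linalg.eigvalsh(Q)
    pos = vals > 1e-10 * max(abs(vals).max(), 1.0)
    gdet = float(np.sum(np.log(vals[pos])))
    return 0.5 * (rank * np.log(tau) + gdet - tau * float(x @ Q @ x)
                  - rank * np.log(2 * np.pi))


class _Adapt:
    """Robbins-Monro step-size adaptation toward a target acceptance."""

    def __init__(self, step: float, target: float = 0.35):
        self.step, self.target = step, target
        self.acc = 0.0
        self.tries = 0

    def record(self, rate: float, weight: int = 1) -> None:
        self.acc += rate * weight
        self.tries += weight

    def adapt(self) -> None:
        if self.tries == 0:
            return
        rate = self.acc / self.tries
        self.step *= float(np.exp(0.66 * (rate - self.target)))
        self.step = float(np.clip(self.step, 1e-4, 20.0))
        self.acc = 0.0
        self.tries = 0


class STModel:
    """Sampler state machine for one ModelSpec on one balanced panel."""

    def __init__(self, O: np.ndarray, E: np.ndarray, spec: ModelSpec,
                 graph: RegionGraph | None = None,
                 likelihood_scale: float = 1.0):
        O = np.asarray(O, dtype=float)
        E = np.asarray(E, dtype=float)
        if O.ndim != 2 or O.size == 0:
            raise ValueError("O must be a non-empty (n, T) panel")
        if O.shape != E.shape:
            raise ValueError("O and E shapes differ")
        if (E < 1e-8).any():
            raise ValueError("cells with expected count < 1e-8 are rejected")
        if (O < 0).any():
            raise ValueError("negative counts")
        self.O, self.E = O, E
        self.n, self.T = O.shape
        self.spec = spec
        self.ls = float(likelihood_scale)
        self._orow, self._ocol = O.sum(axis=1), O.sum(axis=0)

        needs_graph = spec.spatial in ("besag", "bym", "bym2")
        if needs_graph:
            if graph is None:
                raise ValueError("spatial structure requires a RegionGraph")
            if graph.n != self.n:
                raise ValueError("graph size does not match panel")
        self.graph = graph

        # --- structural blocks -------------------------------------------
        self.sp_block: EffectBlock | None = None
        if spec.spatial in ("besag", "bym"):
            self.sp_block = build_icar_precision(graph, scaled=False)
        elif spec.spatial == "bym2":
            self.sp_block = build_icar_precision(graph, scaled=True)

        self.rho = 0.0
        self.ar2_phi = np.array([0.2, 0.1])
        self.tm_block: EffectBlock | None = None
        if spec.temporal_structured != "none":
            # build with a nonzero placeholder rho so the colouring sees
            # the full tridiagonal dependence pattern; Q is refreshed below
            self.tm_block = build_temporal_block(
                spec.temporal_structured, self.T,
                {"rho": 0.5, "phi1": self.ar2_phi[0],
                 "phi2": self.ar2_phi[1]})

        self.int_block: EffectBlock | None = None
        if spec.interaction != "none":
            self.int_block = build_interaction(spec.interaction,
                                               self.sp_block, self.tm_block)
            # spatial-factor eigen info for generalized determinants
            svals = np.linalg.eigvalsh(self.sp_block.Q)
            self._sp_pos = svals[svals > 1e-10 * max(svals.max(), 1.0)]
            if spec.identifiable_interaction:
                if len(graph.components) > 1:
                    raise ValueError("identifiable interaction constraints "
                                     "require a connected graph")
                from scipy.linalg import null_space
                # orthonormal complement of the constant vector in time
                self._bt = null_space(np.ones((1, self.T)))
                self._delta_rank = (self.n - 1) * (self.T - 1)
            else:
                self._bt = None
                self._delta_rank = self.int_block.rank

        # mixing prior needs the scaled-structure eigenvalues
        self._pc_mix: PCMixingPrior | None = None
        if spec.spatial == "bym2":
            sig = self.sp_block.generalized_inverse()
            gam = np.linalg.eigvalsh(sig)
            u, a = spec.priors["omega"].params
            self._pc_mix = PCMixingPrior(gam, U=u, alpha=a)
        self._pc_cor0: PCCor0Prior | None = None
        if "rho" in spec.priors and spec.priors["rho"].family == "pc_cor0":
            u, a = spec.priors["rho"].params
            self._pc_cor0 = PCCor0Prior(self.T, u, a)

        # --- state --------------------------------------------------------
        tot_o, tot_e = O.sum(), E.sum()
        self.alpha = float(np.log((tot_o + 0.5) / (tot_e + 0.5)))
        self.v = np.zeros(self.n)
        self.u = np.zeros(self.n)
        self.ustar = np.zeros(self.n)
        self.gamma = np.zeros(self.T)
        self.phi = np.zeros(self.T)
        self.D = np.zeros((self.n, self.T))
        self.tau_v = self.tau_u = self.tau_b = 10.0
        self.tau_gamma = self.tau_phi = self.tau_delta = 10.0
        self.omega = 0.5

        self._steps = {k: _Adapt(s) for k, s in {
            "alpha": 0.05, "v": 0.6, "u": 0.6, "ustar": 0.6, "gamma": 0.3,
            "phi": 0.3, "delta": 0.6, "tau_b": 0.5, "omega": 0.8,
            "rho": 0.5, "tau_gamma": 0.8, "tau_phi": 0.8, "tau_delta": 0.5,
            "tau_v": 0.8, "tau_u": 0.8, "swap": 0.2, "omega_resc": 1.0,
            "tau_b_resc": 0.5, "delta_swap": 0.3}.items()}
        self._refresh_temporal_Q()
        self._eta = self._compute_eta()

    # --- bookkeeping ------------------------------------------------------
    def b(self) -> np.ndarray:
        s = self.spec.spatial
        if s == "none":
            return np.zeros(self.n)
        if s == "iid":
            return self.v
        if s == "besag":
            return self.u
        if s == "bym":
            return self.u + self.v
        return (np.sqrt(1 - self.omega) * self.v
                + np.sqrt(self.omega) * self.ustar) / np.sqrt(self.tau_b)

    def _compute_eta(self) -> np.ndarray:
        return (self.alpha + self.b()[:, None]
                + (self.gamma + self.phi)[None, :] + self.D)

    def _refresh_temporal_Q(self) -> None:
        # the interaction's Kronecker Q is never materialized here; delta
        # updates and quadratic forms use the factor form directly
        kind = self.spec.temporal_structured
        if kind == "ar1":
            self.tm_block.Q = ar1_precision(self.T, self.rho)
        elif kind == "ar2":
            self.tm_block.Q = ar2_precision(self.T, *self.ar2_phi)
        self._delta_qdiag = None  # depends on Qt; recomputed lazily

    def _interaction_Q_dense(self) -> np.ndarray:
        """Materialized interaction precision at the current rho
        (diagnostics only; the sampler works with the factors)."""
        if self.spec.interaction == "typeIV":
            return np.kron(self.sp_block.Q, self.tm_block.Q)
        if self.spec.interaction == "typeII":
            return np.kron(np.eye(self.n), self.tm_block.Q)
        return self.int_block.Q

    def log_posterior(self) -> float:
        """Full log posterior at the current state (tests/diagnostics)."""
        lp = self.ls * poisson_loglik(self.O, self.E, self._eta)
        pri = self.spec.priors
        m, var = pri["alpha"].params
        lp += normal_logpdf(self.alpha, m, var)
        s = self.spec.spatial
        if s in ("iid", "bym"):
            lp += _gmrf_logdensity(self.v, np.eye(self.n), self.tau_v, self.n)
            lp += self._hyper_logprior("tau_v", self.tau_v)
        if s in ("besag", "bym"):
            blk = self.sp_block
            lp += _gmrf_logdensity(blk.project(self.u), blk.Q, self.tau_u,
                                   blk.rank)
            lp += self._hyper_logprior("tau_u", self.tau_u)
        if s == "bym2":
            lp += _gmrf_logdensity(self.v, np.eye(self.n), 1.0, self.n)
            blk = self.sp_block
            lp += _gmrf_logdensity(blk.project(self.ustar), blk.Q, 1.0,
                                   blk.rank)
            lp += self._hyper_logprior("tau_b", self.tau_b)
            lp += self._pc_mix.logpdf(self.omega)
        if self.tm_block is not None:
            blk = self.tm_block
            lp += _gmrf_logdensity(blk.project(self.gamma), blk.Q,
                                   self.tau_gamma, blk.rank)
            lp += self._hyper_logprior("tau_gamma", self.tau_gamma)
            if "rho" in pri:
                lp += self._rho_logprior(self.rho)
        if self.spec.temporal_iid == "iid":
            lp += _gmrf_logdensity(self.phi, np.eye(self.T), self.tau_phi,
                                   self.T)
            lp += self._hyper_logprior("tau_phi", self.tau_phi)
        if self.int_block is not None:
            blk = self.int_block
            d = blk.project(self.D.ravel())
            lp += _gmrf_logdensity(d, self._interaction_Q_dense(),
                                   self.tau_delta, self._delta_rank)
            lp += self._hyper_logprior("tau_delta", self.tau_delta)
        return float(lp)

    def _hyper_logprior(self, name: str, tau: float) -> float:
        spec = self.spec.priors[name]
        if spec.family == "loggamma":
            return loggamma_logpdf(tau, *spec.params)
        if spec.family == "pc_prec":
            return pc_prec_logpdf(tau, *spec.params)
        raise ValueError(f"unsupported precision prior {spec.family!r}")

    def _rho_logprior(self, rho: float) -> float:
        spec = self.spec.priors["rho"]
        z = np.log((1 + rho) / (1 - rho))
        if spec.family == "pc_cor0":
            # density on rho, plus transform jacobian onto the z scale
            return float(self._pc_cor0.logpdf(rho) + np.log((1 - rho**2) / 2))
        m, var = spec.params
        if self.spec.rho_literal_scale:
            return float(normal_logpdf(rho, m, var)
                         + np.log((1 - rho**2) / 2))
        return float(normal_logpdf(z, m, var))

    # --- likelihood deltas -------------------------------------------------
    def _dll_rows(self, rows: np.ndarray, db: np.ndarray) -> np.ndarray:
        """Likelihood change when b changes by db on the given rows."""
        ee = (self.E[rows] * np.exp(self._eta[rows])).sum(axis=1)
        return self.ls * (self._orow[rows] * db - ee * np.expm1(db))

    def _dll_cols(self, t: int, dg: float) -> float:
        ee = float((self.E[:, t] * np.exp(self._eta[:, t])).sum())
        return self.ls * (self._ocol[t] * dg - ee * np.expm1(dg))

    def _dll_all(self, db_matrix: np.ndarray) -> float:
        ee = self.E * np.exp(self._eta)
        return self.ls * float((self.O * db_matrix
                                - ee * np.expm1(db_matrix)).sum())

    # --- updates ------------------------------------------------------------
    def _up_alpha(self, rng) -> None:
        ad = self._steps["alpha"]
        da = ad.step * rng.standard_normal()
        m, var = self.spec.priors["alpha"].params
        dll = self.ls * (self.O.sum() * da
                         - (self.E * np.exp(self._eta)).sum() * np.expm1(da))
        dlp = dll + normal_logpdf(self.alpha + da, m, var) \
            - normal_logpdf(self.alpha, m, var)
        if np.log(rng.random()) < dlp:
            self.alpha += da
            self._eta += da
            ad.record(1.0)
        else:
            ad.record(0.0)

    def _up_gauss_vector_rows(self, x: np.ndarray, Q: np.ndarray | None,
                              tau: float, colors, coef: float, key: str,
                              rng) -> None:
        """Colour-wise single-site MH for a spatial-length vector whose
        change maps into b with multiplier ``coef``; ``Q=None`` means an
        identity (iid) prior structure."""
        ad = self._steps[key]
        qd = None if Q is None else np.diag(Q)
        for cls in colors:
            dx = ad.step * rng.standard_normal(cls.size)
            db = coef * dx
            dll = self._dll_rows(cls, db)
            if Q is None:
                dpr = -0.5 * tau * (2 * x[cls] * dx + dx * dx)
            else:
                qx = Q[cls] @ x - qd[cls] * x[cls]
                dpr = -0.5 * tau * qd[cls] * (2 * x[cls] * dx + dx * dx) \
                    - tau * dx * qx
            acc = np.log(rng.random(cls.size)) < dll + dpr
            if acc.any():
                idx = cls[acc]
                x[idx] += dx[acc]
                self._eta[idx] += db[acc][:, None]
            ad.record(float(acc.mean()), cls.size)

    def _up_spatial(self, rng) -> None:
        s = self.spec.spatial
        one_color = (np.arange(self.n),)
        if s == "iid":
            self._up_gauss_vector_rows(self.v, None, self.tau_v,
                                       one_color, 1.0, "v", rng)
        elif s == "besag":
            self._up_gauss_vector_rows(self.u, self.sp_block.Q, self.tau_u,
                                       self.sp_block.colors, 1.0, "u", rng)
        elif s == "bym":
            self._up_gauss_vector_rows(self.u, self.sp_block.Q, self.tau_u,
                                       self.sp_block.colors, 1.0, "u", rng)
            self._up_gauss_vector_rows(self.v, None, self.tau_v,
                                       one_color, 1.0, "v", rng)
        elif s == "bym2":
            coef_v = np.sqrt(1 - self.omega) / np.sqrt(self.tau_b)
            coef_u = np.sqrt(self.omega) / np.sqrt(self.tau_b)
            self._up_gauss_vector_rows(self.v, None, 1.0,
                                       one_color, coef_v, "v", rng)
            self._up_gauss_vector_rows(self.ustar, self.sp_block.Q, 1.0,
                                       self.sp_block.colors, coef_u,
                                       "ustar", rng)
            self._sweep_count = getattr(self, "_sweep_count", 0) + 1
            if self._sweep_count % 3 == 0:
                self._refresh_bym2_split(rng)
            self._up_tau_b(rng)
            self._up_omega(rng)
            self._up_bym2_rescale(rng)
        # conjugate / MH precision updates for the classic blocks
        if s in ("iid", "bym"):
            self.tau_v = self._update_precision(
                "tau_v", float(self.v @ self.v), self.n, rng)
        if s in ("besag", "bym"):
            self.tau_u = self._update_precision(
                "tau_u", float(self.u @ self.sp_block.Q @ self.u),
                self.sp_block.rank, rng)

    def _update_precision(self, name: str, q: float, rank: int,
                          rng) -> float:
        """Precision update for a raw GMRF with quadratic form q = x'Qx.

        loggamma priors are conjugate (exact Gibbs).  PC priors use an
        independence Metropolis proposal drawn from the Gamma likelihood
        factor tau^{rank/2} e^{-tau q/2}; the acceptance ratio then
        reduces to the PC prior ratio, which keeps acceptance high even
        when tau and the latent field are strongly coupled."""
        spec = self.spec.priors[name]
        tau = getattr(self, name)
        if spec.family == "loggamma":
            a, b = spec.params
            return float(rng.gamma(a + rank / 2.0, 1.0 / (b + q / 2.0)))
        if q > 1e-12:
            tau_new = float(rng.gamma(rank / 2.0 + 1.0, 2.0 / q))
            dlp = pc_prec_logpdf(tau_new, *spec.params) \
                - pc_prec_logpdf(tau, *spec.params)
            if np.log(rng.random()) < dlp:
                return tau_new
            return tau
        ad = self._steps[name]
        lt = np.log(tau)
        lt_new = lt + ad.step * rng.standard_normal()
        tau_new = float(np.exp(lt_new))
        dlp = 0.5 * rank * (lt_new - lt) - 0.5 * q * (tau_new - tau) \
            + pc_prec_logpdf(tau_new, *spec.params) \
            - pc_prec_logpdf(tau, *spec.params) + (lt_new - lt)
        if np.log(rng.random()) < dlp:
            ad.record(1.0)
            return tau_new
        ad.record(0.0)
        return tau

    def _up_tau_b(self, rng) -> None:
        ad = self._steps["tau_b"]
        lt = np.log(self.tau_b)
        lt_new = lt + ad.step * rng.standard_normal()
        tau_new = float(np.exp(lt_new))
        scale = np.sqrt(self.tau_b / tau_new)  # b' = b * scale
        b = self.b()
        dll = self._dll_all((scale - 1.0) * b[:, None]
                            * np.ones((1, self.T)))
        spec = self.spec.priors["tau_b"]
        dlp = dll + pc_prec_logpdf(tau_new, *spec.params) \
            - pc_prec_logpdf(self.tau_b, *spec.params) + (lt_new - lt)
        if np.log(rng.random()) < dlp:
            self.tau_b = tau_new
            self._eta += ((scale - 1.0) * b)[:, None]
            ad.record(1.0)
        else:
            ad.record(0.0)

    def _up_omega(self, rng) -> None:
        ad = self._steps["omega"]
        w = self.omega
        z = np.log(w / (1 - w))
        z_new = z + ad.step * rng.standard_normal()
        w_new = float(1 / (1 + np.exp(-z_new)))
        b_old = self.b()
        b_new = (np.sqrt(1 - w_new) * self.v
                 + np.sqrt(w_new) * self.ustar) / np.sqrt(self.tau_b)
        db = b_new - b_old
        dll = self._dll_all(db[:, None] * np.ones((1, self.T)))
        dlp = dll + self._pc_mix.logpdf(w_new) - self._pc_mix.logpdf(w) \
            + np.log(w_new * (1 - w_new)) - np.log(w * (1 - w))
        if np.log(rng.random()) < dlp:
            self.omega = w_new
            self._eta += db[:, None]
            ad.record(1.0)
        else:
            ad.record(0.0)

    def _up_temporal(self, rng) -> None:
        blk = self.tm_block
        ad = self._steps["gamma"]
        qd = np.diag(blk.Q)
        for cls in blk.colors:
            for t in cls:  # T is tiny; per-site loop is fine
                dg = ad.step * rng.standard_normal()
                dll = self._dll_cols(t, dg)
                qx = float(blk.Q[t] @ self.gamma) - qd[t] * self.gamma[t]
                dpr = -0.5 * self.tau_gamma * qd[t] \
                    * (2 * self.gamma[t] * dg + dg * dg) \
                    - self.tau_gamma * dg * qx
                if np.log(rng.random()) < dll + dpr:
                    self.gamma[t] += dg
                    self._eta[:, t] += dg
                    ad.record(1.0)
                else:
                    ad.record(0.0)
        self.tau_gamma = self._update_precision(
            "tau_gamma", float(self.gamma @ blk.Q @ self.gamma),
            blk.rank, rng)
        if self.spec.temporal_structured == "ar1":
            self._up_rho(rng)

    def _delta_quad(self, qt: np.ndarray) -> float:
        if self.spec.interaction == "typeIV":
            m = self.sp_block.Q @ self.D @ qt
        elif self.spec.interaction == "typeII":
            m = self.D @ qt
        elif self.spec.interaction == "typeI":
            return float((self.D * self.D).sum())
        else:
            return float(self.D.ravel() @ self.int_block.Q @ self.D.ravel())
        return float((self.D * m).sum())

    def _up_rho(self, rng) -> None:
        ad = self._steps["rho"]
        rho = self.rho
        z = np.log((1 + rho) / (1 - rho))
        z_new = z + ad.step * rng.standard_normal()
        rho_new = float(np.tanh(z_new / 2))
        q_old, q_new = self.tm_block.Q, ar1_precision(self.T, rho_new)
        ldet_old = -(self.T - 1) * np.log1p(-rho * rho)
        ldet_new = -(self.T - 1) * np.log1p(-rho_new * rho_new)
        g = self.gamma
        dlp = 0.5 * (ldet_new - ldet_old) \
            - 0.5 * self.tau_gamma * float(g @ (q_new - q_old) @ g) \
            + self._rho_logprior(rho_new) - self._rho_logprior(rho)
        if self.int_block is not None and self.spec.interaction in (
                "typeII", "typeIV"):
            if self.spec.identifiable_interaction:
                # restricted to the doubly-centred subspace S_s (x) S_t,
                # the interaction precision is a Kronecker of restricted
                # factors; its rho-dependent log-determinant is
                # (n-1) * ln det(B_t' Q_t B_t)
                bt = self._bt
                ld_old = np.linalg.slogdet(bt.T @ q_old @ bt)[1]
                ld_new = np.linalg.slogdet(bt.T @ q_new @ bt)[1]
                dlp += 0.5 * (self.n - 1) * (ld_new - ld_old)
            else:
                rank_s = self.sp_block.rank \
                    if self.spec.interaction == "typeIV" else self.n
                dlp += 0.5 * rank_s * (ldet_new - ldet_old)
            dlp -= 0.5 * self.tau_delta * (self._delta_quad(q_new)
                                           - self._delta_quad(q_old))
        if np.log(rng.random()) < dlp:
            self.rho = rho_new
            self._refresh_temporal_Q()
            ad.record(1.0)
        else:
            ad.record(0.0)

    def _up_phi(self, rng) -> None:
        ad = self._steps["phi"]
        for t in range(self.T):
            dp = ad.step * rng.standard_normal()
            dll = self._dll_cols(t, dp)
            dpr = -0.5 * self.tau_phi * (2 * self.phi[t] * dp + dp * dp)
            if np.log(rng.random()) < dll + dpr:
                self.phi[t] += dp
                self._eta[:, t] += dp
                ad.record(1.0)
            else:
                ad.record(0.0)
        self.tau_phi = self._update_precision(
            "tau_phi", float(self.phi @ self.phi), self.T, rng)

    def _up_delta(self, rng) -> None:
        blk = self.int_block
        ad = self._steps["delta"]
        d = self.D.ravel()
        qt = self.tm_block.Q
        e_flat = self.E.ravel()
        o_flat = self.O.ravel()
        qdiag_by_cls = getattr(self, "_delta_qdiag", None)
        if qdiag_by_cls is None:
            itype = self.spec.interaction
            if itype == "typeIV":
                full = np.outer(np.diag(self.sp_block.Q),
                                np.diag(qt)).ravel()
            elif itype == "typeII":
                full = np.tile(np.diag(qt), self.n)
            elif itype == "typeI":
                full = np.ones(self.n * self.T)
            else:
                full = np.diag(blk.Q)
            qdiag_by_cls = [full[cls] for cls in blk.colors]
            self._delta_qdiag = qdiag_by_cls
        for k, cls in enumerate(blk.colors):
            qdiag = qdiag_by_cls[k]
            if self.spec.interaction == "typeIV":
                qdotd = (self.sp_block.Q @ self.D @ qt).ravel()[cls]
            elif self.spec.interaction == "typeII":
                qdotd = (self.D @ qt).ravel()[cls]
            elif self.spec.interaction == "typeI":
                qdotd = d[cls]
            else:
                qdotd = (blk.Q[cls] @ d)
            dd = ad.step * rng.standard_normal(cls.size)
            eta_flat = self._eta.ravel()
            dll = self.ls * (o_flat[cls] * dd - e_flat[cls]
                             * np.exp(eta_flat[cls]) * np.expm1(dd))
            dpr = -0.5 * self.tau_delta * qdiag * dd * dd \
                - self.tau_delta * dd * qdotd
            acc = np.log(rng.random(cls.size)) < dll + dpr
            if acc.any():
                idx = cls[acc]
                d[idx] += dd[acc]
                self.D = d.reshape(self.n, self.T)
                self._eta.ravel()[idx] += dd[acc]
            ad.record(float(acc.mean()), cls.size)
        self.tau_delta = self._update_precision(
            "tau_delta", self._delta_quad(self.tm_block.Q),
            self._delta_rank, rng)

    def _up_bym2_rescale(self, rng, repeats: int = 3) -> None:
        """Joint reparameterization moves for (omega, tau_b).

        Proposing omega' (or tau_b') while rescaling v and u* so that
        the composite field b is unchanged leaves the likelihood fixed;
        only the standard-normal / scaled-ICAR priors, the hyperpriors,
        and the transform Jacobian enter the ratio.  This decouples the
        mixing parameter from the latent field and cuts its
        autocorrelation dramatically.  Quadratic forms scale by the
        squared factors, so the repeats cost no matrix work."""
        spec_b = self.spec.priors["tau_b"]
        rank = self.sp_block.rank
        qv = float(self.v @ self.v)
        qu = float(self.ustar @ self.sp_block.Q @ self.ustar)
        sv_tot = su_tot = 1.0
        for _ in range(repeats):
            # --- omega move ---
            ad = self._steps["omega_resc"]
            w = self.omega
            z = np.log(w / (1 - w))
            z_new = z + ad.step * rng.standard_normal()
            w_new = float(1 / (1 + np.exp(-z_new)))
            sv = np.sqrt((1 - w) / (1 - w_new))
            su = np.sqrt(w / w_new)
            dlp = -0.5 * (sv * sv - 1) * qv - 0.5 * (su * su - 1) * qu \
                + self.n * np.log(sv) + rank * np.log(su) \
                + self._pc_mix.logpdf(w_new) - self._pc_mix.logpdf(w) \
                + np.log(w_new * (1 - w_new)) - np.log(w * (1 - w))
            if np.log(rng.random()) < dlp:
                self.omega = w_new
                qv *= sv * sv
                qu *= su * su
                sv_tot *= sv
                su_tot *= su
                ad.record(1.0)
            else:
                ad.record(0.0)
            # --- tau_b move ---
            ad = self._steps["tau_b_resc"]
            lt = np.log(self.tau_b)
            lt_new = lt + ad.step * rng.standard_normal()
            tau_new = float(np.exp(lt_new))
            s = np.sqrt(tau_new / self.tau_b)   # v,u* scale so b is fixed
            dlp = -0.5 * (s * s - 1) * (qv + qu) \
                + (self.n + rank) * np.log(s) \
                + pc_prec_logpdf(tau_new, *spec_b.params) \
                - pc_prec_logpdf(self.tau_b, *spec_b.params) \
                + (lt_new - lt)
            if np.log(rng.random()) < dlp:
                self.tau_b = tau_new
                qv *= s * s
                qu *= s * s
                sv_tot *= s
                su_tot *= s
                ad.record(1.0)
            else:
                ad.record(0.0)
        if sv_tot != 1.0:
            self.v *= sv_tot
        if su_tot != 1.0:
            self.ustar *= su_tot

    def _refresh_bym2_split(self, rng) -> None:
        """Exact Gibbs refresh of the (v, u*) split at fixed b.

        The likelihood depends on the composite field only, so given b
        and the hyperparameters the conditional of v is Gaussian with
        precision I + ((1-w)/w) Q, subject to the lifted sum-to-zero
        constraints of u*.  Redrawing the split exactly decorrelates
        omega and tau_b from the latent fields."""
        w = self.omega
        if not 1e-4 < w < 1 - 1e-4:
            return
        q = self.sp_block.Q
        r = (1 - w) / w
        prec = r * q + np.eye(self.n)
        c_vec = np.sqrt(1 - w) * self.v + np.sqrt(w) * self.ustar
        rhs = (np.sqrt(1 - w) / w) * (q @ c_vec)
        low = cho_factor(prec, lower=True)
        mean = cho_solve(low, rhs)
        z = rng.standard_normal(self.n)
        v_s = mean + solve_triangular(low[0], z, lower=True, trans="T")
        a = self.sp_block.constraints
        if a.size:
            target = (a @ c_vec) / np.sqrt(1 - w)
            sig_at = cho_solve(low, a.T)
            corr = sig_at @ np.linalg.solve(a @ sig_at,
                                            a @ v_s - target)
            v_s = v_s - corr
        self.v = v_s
        self.ustar = (c_vec - np.sqrt(1 - w) * v_s) / np.sqrt(w)

    def _up_delta_spatial_swap(self, rng) -> None:
        """Shear move between the interaction and the spatial block.

        A per-city constant-in-time component of delta is confounded
        with b when the interaction's temporal factor is proper; this
        move transfers a fraction kappa of the per-city time-means of
        delta into the unstructured spatial vector (eta unchanged, unit
        Jacobian), letting the chain settle the allocation quickly."""
        s = self.spec.spatial
        if s not in ("iid", "bym", "bym2"):
            return
        if self.spec.identifiable_interaction:
            return  # per-city means are pinned to zero; nothing to trade
        if s == "bym2":
            coef = np.sqrt(1 - self.omega) / np.sqrt(self.tau_b)
            tau_eff = 1.0
            if coef <= 1e-8:
                return
        else:
            coef, tau_eff = 1.0, self.tau_v
        ad = self._steps["delta_swap"]
        kappa = ad.step * rng.standard_normal()
        m = self.D.mean(axis=1)
        d_new = self.D - kappa * m[:, None]
        v_new = self.v + kappa * m / coef
        qt = self.tm_block.Q
        d_old_mat = self.D
        self.D = d_new
        q_new = self._delta_quad(qt)
        self.D = d_old_mat
        q_old = self._delta_quad(qt)
        dlp = -0.5 * self.tau_delta * (q_new - q_old) \
            - 0.5 * tau_eff * float(v_new @ v_new - self.v @ self.v)
        if np.log(rng.random()) < dlp:
            self.D = d_new
            self.v = v_new
            ad.record(1.0)
        else:
            ad.record(0.0)

    def _up_swaps(self, rng) -> None:
        """Likelihood-preserving moves along confounded directions.

        The intercept trades a constant against the mean of phi, gamma,
        or the iid spatial vector; eta is unchanged, only the Gaussian
        priors discriminate, so these moves decorrelate alpha from the
        block means at negligible cost."""
        m, var = self.spec.priors["alpha"].params
        ad = self._steps["swap"]

        def try_swap(dprior_fn, apply_fn) -> None:
            c = ad.step * rng.standard_normal()
            dlp = dprior_fn(c) + normal_logpdf(self.alpha + c, m, var) \
                - normal_logpdf(self.alpha, m, var)
            if np.log(rng.random()) < dlp:
                self.alpha += c
                apply_fn(c)
                ad.record(1.0)
            else:
                ad.record(0.0)

        if self.spec.temporal_iid == "iid":
            def dpr(c):
                return -0.5 * self.tau_phi * float(
                    ((self.phi - c) ** 2 - self.phi ** 2).sum())

            def app(c):
                self.phi -= c
            try_swap(dpr, app)
        if self.tm_block is not None and self.tm_block.n_constraints == 0:
            q = self.tm_block.Q

            def dpr(c):
                g2 = self.gamma - c
                return -0.5 * self.tau_gamma * float(g2 @ q @ g2
                                                     - self.gamma @ q
                                                     @ self.gamma)

            def app(c):
                self.gamma -= c
            try_swap(dpr, app)
        s = self.spec.spatial
        if s in ("iid", "bym", "bym2"):
            if s == "bym2":
                coef = np.sqrt(1 - self.omega) / np.sqrt(self.tau_b)
                tau_eff = 1.0
            else:
                coef, tau_eff = 1.0, self.tau_v
            if coef > 1e-8:
                def dpr(c):
                    dv = c / coef
                    return -0.5 * tau_eff * float(
                        ((self.v - dv) ** 2 - self.v ** 2).sum())

                def app(c):
                    self.v -= c / coef
                try_swap(dpr, app)

    # --- constraints ---------------------------------------------------------
    def _recenter(self) -> None:
        s = self.spec.spatial
        if s in ("besag", "bym"):
            m = self.u.mean()
            if len(self.graph.components) == 1:
                self.u -= m
                self.alpha += m  # likelihood-preserving transfer
            else:
                self.u = self.sp_block.project(self.u)
        elif s == "bym2":
            self.ustar = self.sp_block.project(self.ustar)
        if self.tm_block is not None and self.tm_block.n_constraints:
            m = self.gamma.mean()
            self.gamma = self.tm_block.project(self.gamma)
            self.alpha += m
        if self.int_block is not None:
            if self.spec.identifiable_interaction:
                self._double_center_delta()
            elif self.int_block.n_constraints:
                if self.spec.interaction in ("typeIII", "typeIV") and \
                        self.sp_block.n_constraints and \
                        len(self.graph.components) == 1:
                    col_means = self.D.mean(axis=0)
                    self.D -= col_means[None, :]
                    if self.spec.temporal_iid == "iid":
                        self.phi += col_means
                    else:
                        self.gamma += col_means
                if self.spec.interaction in ("typeII", "typeIV") and \
                        self.tm_block.n_constraints:
                    row_means = self.D.mean(axis=1)
                    self.D -= row_means[:, None]
                    if s == "bym":
                        self.v += row_means
                    elif s == "besag":
                        self.u += row_means
                # exact projection for anything not handled above
                self.D = self.int_block.project(self.D.ravel()) \
                    .reshape(self.n, self.T)
        self._eta = self._compute_eta()

    def _double_center_delta(self) -> None:
        """Centre delta over cities within each year and over years
        within each city, transferring the removed means into the
        temporal and spatial blocks so eta is unchanged."""
        col_means = self.D.mean(axis=0)
        self.D = self.D - col_means[None, :]
        if self.spec.temporal_iid == "iid":
            self.phi += col_means
        else:
            self.gamma += col_means
        row_means = self.D.mean(axis=1)
        self.D = self.D - row_means[:, None]
        s = self.spec.spatial
        if s == "bym2":
            coef_v = np.sqrt(1 - self.omega) / np.sqrt(self.tau_b)
            coef_u = np.sqrt(self.omega) / np.sqrt(self.tau_b)
            if coef_v > 1e-8:
                self.v += row_means / coef_v
            else:
                self.ustar += row_means / coef_u
        elif s in ("bym", "iid"):
            self.v += row_means
        elif s == "besag":
            self.u += row_means

    # --- driver --------------------------------------------------------------
    def sweep(self, rng, adapting: bool) -> None:
        self._up_alpha(rng)
        if self.spec.spatial != "none":
            self._up_spatial(rng)
        if self.tm_block is not None:
            self._up_temporal(rng)
        if self.spec.temporal_iid == "iid":
            self._up_phi(rng)
        if self.int_block is not None:
            self._up_delta(rng)
            self._up_delta_spatial_swap(rng)
        self._up_swaps(rng)
        self._recenter()
        if adapting:
            self._it_since_adapt = getattr(self, "_it_since_adapt", 0) + 1
            if self._it_since_adapt >= 50:
                for ad in self._steps.values():
                    ad.adapt()
                self._it_since_adapt = 0

    def state_record(self) -> dict[str, float | np.ndarray]:
        rec: dict[str, float | np.ndarray] = {
            "alpha": self.alpha, "eta": self._eta.copy(),
            "b": self.b().copy(), "gamma": self.gamma.copy(),
            "phi": self.phi.copy(), "delta": self.D.copy()}
        s = self.spec.spatial
        if s in ("iid", "bym"):
            rec["tau_v"] = self.tau_v
        if s in ("besag", "bym"):
            rec["tau_u"] = self.tau_u
        if s == "bym2":
            rec["tau_b"] = self.tau_b
            rec["omega"] = self.omega
        if self.tm_block is not None:
            rec["tau_gamma"] = self.tau_gamma
            if self.spec.temporal_structured == "ar1":
                rec["rho"] = self.rho
        if self.spec.temporal_iid == "iid":
            rec["tau_phi"] = self.tau_phi
        if self.int_block is not None:
            rec["tau_delta"] = self.tau_delta
        return rec

    def jitter_init(self, rng) -> None:
        """Overdispersed chain initialization."""
        self.alpha += 0.2 * rng.standard_normal()
        for name in ("tau_v", "tau_u", "tau_b", "tau_gamma", "tau_phi",
                     "tau_delta"):
            setattr(self, name, float(getattr(self, name)
                                      * np.exp(0.5 * rng.standard_normal())))
        self.omega = float(np.clip(rng.beta(2, 2), 0.05, 0.95))
        self._eta = self._compute_eta()


@dataclass
class FitResult:
    """Posterior draws and summaries from :func:`fit_mcmc`."""

    spec: ModelSpec
    draws: dict[str, np.ndarray]       # name -> (chains, kept, ...)
    O: np.ndarray
    E: np.ndarray
    seed: int
    chains: int
    iterations: int
    burn_in: int
    thin: int
    rhat: dict[str, float] = dc_field(default_factory=dict)
    ess: dict[str, float] = dc_field(default_factory=dict)
    converged: bool = True

    HYPER_NAMES = ("alpha", "tau_v", "tau_u", "tau_b", "omega", "rho",
                   "tau_gamma", "tau_phi", "tau_delta")

    def scalar_names(self) -> list[str]:
        return [k for k in self.HYPER_NAMES if k in self.draws]

    def pooled(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.scalar_names():
            x = self.pooled(name)
            rows.append({
                "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                "q2.5": np.percentile(x, 2.5),
                "q97.5": np.percentile(x, 97.5),
                "rhat": self.rhat.get(name, np.nan),
                "ess": self.ess.get(name, np.nan)})
        return pd.DataFrame(rows)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.pooled(name)
        lo = 100 * (1 - level) / 2
        return (float(np.percentile(x, lo)),
                float(np.percentile(x, 100 - lo)))

    def theta_mean(self) -> np.ndarray:
        """Posterior mean of the relative risk theta_it."""
        return np.exp(self.pooled("eta")).mean(axis=0)

    def delta_mean(self) -> np.ndarray:
        return self.pooled("delta").mean(axis=0)


def fit_mcmc(O: np.ndarray, E: np.ndarray, spec: ModelSpec,
             graph: RegionGraph | None = None, chains: int = 2,
             iterations: int = 20_000, burn_in: int = 10_000, thin: int = 5,
             seed: int | None = None,
             likelihood_scale: float = 1.0) -> FitResult:
    """Run Metropolis-within-Gibbs chains and collect posterior draws.

    ``seed`` is required; chains use independent child seeds.  R-hat
    (split) and effective sample size are computed for every scalar
    hyperparameter; ``converged`` is False when any R-hat > 1.05.
    """
    if seed is None:
        raise ValueError("seed is required")
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence checks")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    per_chain: list[list[dict]] = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        model = STModel(O, E, spec, graph, likelihood_scale)
        model.jitter_init(rng)
        kept: list[dict] = []
        for it in range(iterations):
            model.sweep(rng, adapting=it < burn_in)
            if it >= burn_in and (it - burn_in) % thin == 0:
                kept.append(model.state_record())
        per_chain.append(kept)
    k = len(per_chain[0])
    names = per_chain[0][0].keys()
    draws: dict[str, np.ndarray] = {}
    for name in names:
        sample = np.asarray(per_chain[0][0][name])
        arr = np.empty((chains, k, *sample.shape))
        for c in range(chains):
            for i, rec in enumerate(per_chain[c]):
                arr[c, i] = rec[name]
        draws[name] = arr

    fit = FitResult(spec=spec, draws=draws, O=np.asarray(O, float),
                    E=np.asarray(E, float), seed=seed, chains=chains,
                    iterations=iterations, burn_in=burn_in, thin=thin)
    import arviz as az
    for name in fit.scalar_names():
        x = draws[name]
        fit.rhat[name] = float(az.rhat(az.convert_to_dataset(x))["x"].values)
        fit.ess[name] = float(az.ess(az.convert_to_dataset(x))["x"].values)
    fit.converged = all(np.isnan(r) or r <= RHAT_LIMIT
                        for r in fit.rhat.values())
    if not fit.converged:
        logger.warning("non-convergence: max R-hat = %.3f",
                       max(fit.rhat.values()))
    return fit
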
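"""Gaussian Markov random field building blocks.

Each latent effect in the model family — structured space (ICAR /
scaled ICAR), unstructured space (iid), structured time (RW1, RW2,
AR(1), AR(2)), unstructured time (iid), and the four Knorr-Held
space-time interaction types — is described by an :class:`EffectBlock`
holding its precision structure Q, rank, sum-to-zero constraint set and
a graph colouring of its conditional-dependence graph (used by the
sampler for valid simultaneous single-site updates).

Improper structures carry explicit constraints spanning their null
space; the scaled ICAR follows the standard convention that the
geometric mean of the marginal variances of the constrained generalized
inverse equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ..geo_weights import RegionGraph

__all__ = ["EffectBlock", "build_icar_precision", "build_temporal_block",
           "build_interaction", "ar1_precision", "rw_precision",
           "scaled_icar", "icar_scale_factor", "INTERACTION_TYPES"]

INTERACTION_TYPES = ("typeI", "typeII", "typeIII", "typeIV")


@dataclass
class EffectBlock:
    """Precision structure of one latent Gaussian effect vector."""

    kind: str
    dim: int
    Q: np.ndarray = field(repr=False)
    rank: int
    constraints: np.ndarray = field(repr=False)  # (k, dim), rows span null(Q)
    scale_factor: float = 1.0
    colors: tuple[np.ndarray, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.Q.shape != (self.dim, self.dim):
            raise ValueError("Q shape mismatch")
        if not self.colors:
            self.colors = _color_from_precision(self.Q)

    @property
    def n_constraints(self) -> int:
        return self.constraints.shape[0] if self.constraints.size else 0

    def project(self, x: np.ndarray) -> np.ndarray:
        """Project x onto the orthogonal complement of the constraints."""
        a = self.constraints
        if not a.size:
            return x
        if not hasattr(self, "_proj_cache"):
            # A^T (A A^T)^+ A, cached; constraint rows may be dependent
            self._proj_cache = a.T @ np.linalg.pinv(a @ a.T) @ a
        return x - self._proj_cache @ x

    def quad_form(self, x: np.ndarray) -> float:
        return float(x @ self.Q @ x)

    def generalized_inverse(self) -> np.ndarray:
        """Constrained generalized inverse (pseudo-inverse of Q)."""
        return np.linalg.pinv(self.Q, hermitian=True, rcond=1e-10)

    def sample(self, rng: np.random.Generator, tau: float = 1.0) -> np.ndarray:
        """Draw from N(0, (tau Q)^-) subject to the constraints."""
        vals, vecs = np.linalg.eigh(self.Q)
        pos = vals > 1e-10 * max(vals.max(), 1.0)
        z = rng.standard_normal(int(pos.sum()))
        x = vecs[:, pos] @ (z / np.sqrt(vals[pos] * tau))
        return self.project(x)


def _color_from_precision(q: np.ndarray) -> tuple[np.ndarray, ...]:
    """Greedy colouring of the conditional-dependence graph of Q."""
    n = q.shape[0]
    off = np.abs(q - np.diag(np.diag(q))) > 1e-12
    if not off.any():
        return (np.arange(n),)
    g = nx.from_numpy_array(off)
    coloring = nx.greedy_color(g, strategy="largest_first")
    k = max(coloring.values()) + 1
    return tuple(np.array([i for i in range(n) if coloring[i] == c])
                 for c in range(k))


def _graph_laplacian(graph: RegionGraph) -> np.ndarray:
    a = graph.adjacency_matrix().toarray()
    return np.diag(a.sum(axis=1)) - a


def _component_constraints(graph: RegionGraph) -> np.ndarray:
    """One sum-to-zero constraint per connected component."""
    idx = graph.index()
    rows = []
    for comp in graph.components:
        v = np.zeros(graph.n)
        for rid in comp:
            v[idx[rid]] = 1.0
        rows.append(v)
    return np.array(rows)


def icar_scale_factor(graph: RegionGraph) -> float:
    """Geometric mean of marginal variances of the constrained ICAR.

    Singleton components contribute no variability (their effect is
    pinned to zero by the constraint) and are excluded from the mean.
    """
    q = _graph_laplacian(graph)
    sig = np.linalg.pinv(q, hermitian=True, rcond=1e-10)
    mvar = np.diag(sig)
    keep = mvar > 1e-12
    if not keep.any():
        raise ValueError("graph has no non-singleton components")
    return float(np.exp(np.mean(np.log(mvar[keep]))))


def build_icar_precision(graph: RegionGraph, scaled: bool = True) -> EffectBlock:
    """ICAR (Besag) precision Q = D - A with per-component constraints.

    When ``scaled``, Q is multiplied by the geometric-mean marginal
    variance so the constrained generalized inverse of the scaled Q has
    geometric-mean marginal variance 1.
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    q = _graph_laplacian(graph)
    factor = icar_scale_factor(graph) if scaled else 1.0
    return EffectBlock(
        kind="besag_scaled" if scaled else "besag",
        dim=graph.n,
        Q=q * factor,
        rank=graph.n - len(graph.components),
        constraints=_component_constraints(graph),
        scale_factor=factor,
    )


def scaled_icar(graph: RegionGraph) -> EffectBlock:
    return build_icar_precision(graph, scaled=True)


def rw_precision(T: int, order: int) -> np.ndarray:
    d = np.eye(T)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


def ar1_precision(T: int, rho: float) -> np.ndarray:
    """Stationary AR(1) precision in the unit-marginal-variance
    parameterization (marginal variances all equal 1 for |rho| < 1)."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    q = np.zeros((T, T))
    idx = np.arange(T)
    q[idx, idx] = 1 + rho * rho
    q[0, 0] = q[-1, -1] = 1.0
    q[idx[:-1], idx[1:]] = -rho
    q[idx[1:], idx[:-1]] = -rho
    return q / (1 - rho * rho)


def _ar2_covariance(T: int, phi1: float, phi2: float) -> np.ndarray:
    """Unit-marginal-variance stationary AR(2) autocovariance (Toeplitz)."""
    if not (abs(phi2) < 1 and phi2 + phi1 < 1 and phi2 - phi1 < 1):
        raise ValueError("AR(2) coefficients outside the stationary region")
    acf = np.empty(T)
    acf[0] = 1.0
    if T > 1:
        acf[1] = phi1 / (1 - phi2)
    for k in range(2, T):
        acf[k] = phi1 * acf[k - 1] + phi2 * acf[k - 2]
    from scipy.linalg import toeplitz
    return toeplitz(acf)


def ar2_precision(T: int, phi1: float, phi2: float) -> np.ndarray:
    return np.linalg.inv(_ar2_covariance(T, phi1, phi2))


def build_temporal_block(kind: str, T: int, params: dict | None = None
                         ) -> EffectBlock:
    """Temporal structured block: rw1/rw2 (improper) or ar1/ar2 (proper)."""
    params = params or {}
    if kind in ("rw1", "rw2"):
        order = 1 if kind == "rw1" else 2
        if T < order + 1:
            raise ValueError(f"{kind} needs T >= {order + 1}")
        q = rw_precision(T, order)
        if order == 1:
            cons = np.ones((1, T))
        else:
            cons = np.vstack([np.ones(T), np.arange(T, dtype=float)])
        return EffectBlock(kind=kind, dim=T, Q=q, rank=T - order,
                           constraints=cons)
    if kind == "ar1":
        if T < 2:
            raise ValueError("ar1 needs T >= 2")
        rho = params.get("rho", 0.0)
        return EffectBlock(kind="ar1", dim=T, Q=ar1_precision(T, rho),
                           rank=T, constraints=np.empty((0, T)))
    if kind == "ar2":
        if T < 3:
            raise ValueError("ar2 needs T >= 3")
        q = ar2_precision(T, params.get("phi1", 0.0), params.get("phi2", 0.0))
        return EffectBlock(kind="ar2", dim=T, Q=q, rank=T,
                           constraints=np.empty((0, T)))
    raise ValueError(f"unknown temporal kind {kind!r}")


def _null_basis(block: EffectBlock) -> np.ndarray:
    """Orthonormal basis (columns) of the structure's null space."""
    if block.n_constraints == 0:
        return np.empty((block.dim, 0))
    q, _ = np.linalg.qr(block.constraints.T)
    return q[:, :np.linalg.matrix_rank(block.constraints)]


def build_interaction(int_type: str, spatial: EffectBlock,
                      temporal: EffectBlock) -> EffectBlock:
    """Knorr-Held space-time interaction block over nT cells (i-major).

    * Type I   — unstructured x unstructured: identity precision;
    * Type II  — unstructured space x structured time: I_n (x) Q_time;
    * Type III — structured space x unstructured time: Q_space (x) I_T;
    * Type IV  — structured x structured: Q_space (x) Q_time.

    Constraints are the Kronecker lifts of the factor null spaces
    (e.g. per-year sum-to-zero over each spatial component for a
    Besag x AR(1) Type IV).
    """
    n, big_t = spatial.dim, temporal.dim
    eye_n, eye_t = np.eye(n), np.eye(big_t)
    if int_type == "typeI":
        return EffectBlock(kind="typeI", dim=n * big_t, Q=np.eye(n * big_t),
                           rank=n * big_t,
                           constraints=np.empty((0, n * big_t)),
                           colors=(np.arange(n * big_t),))
    if int_type == "typeII":
        q = np.kron(eye_n, temporal.Q)
        rank = n * temporal.rank
        cons = [np.kron(eye_n[i], c) for i in range(n)
                for c in temporal.constraints]
    elif int_type == "typeIII":
        q = np.kron(spatial.Q, eye_t)
        rank = spatial.rank * big_t
        cons = [np.kron(c, eye_t[t]) for t in range(big_t)
                for c in spatial.constraints]
    elif int_type == "typeIV":
        q = np.kron(spatial.Q, temporal.Q)
        rank = spatial.rank * temporal.rank
        cons = [np.kron(c, eye_t[t]) for t in range(big_t)
                for c in spatial.constraints]
        cons += [np.kron(eye_n[i], c) for i in range(n)
                 for c in temporal.constraints]
    else:
        raise ValueError(f"unknown interaction type {int_type!r}")
    constraints = np.array(cons) if cons else np.empty((0, n * big_t))
    return EffectBlock(kind=int_type, dim=n * big_t, Q=q, rank=rank,
                       constraints=constraints)
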
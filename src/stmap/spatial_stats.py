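"""Spatial and spatiotemporal autocorrelation statistics.

Implements the classical areal autocorrelation toolkit on a
:class:`~stmap.geo_weights.WeightsMatrix` / :class:`~stmap.geo_weights.STWeights`:

* global Moran's I with conditional-randomization inference,
* local Moran (LISA) with HH/LL/HL/LH cluster-outlier typing,
* Getis-Ord Gi* hotspot z-scores (self-included, binary weights),
* a spatiotemporal Moran's I over joint space-time cells.

Two-sided permutation pseudo p-values use
``p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geo_weights import RegionGraph, STWeights, WeightsMatrix

__all__ = ["MoranResult", "LISAResult", "GiStarResult", "STMoranResult",
           "global_morans_i", "lisa", "gi_star", "st_morans_i"]

GI_BINS = ("hot99", "hot95", "hot90", "cold90", "cold95", "cold99", "NS")
_Z90, _Z95, _Z99 = 1.645, 1.960, 2.576


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    z: float
    p: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class LISAResult:
    local_i: np.ndarray
    p: np.ndarray
    category: tuple[str, ...]
    alpha: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class GiStarResult:
    z: np.ndarray
    p: np.ndarray
    bin: tuple[str, ...]


@dataclass(frozen=True)
class STMoranResult:
    I: float
    z: float
    p: float
    n: int
    T: int
    scheme: str
    n_perm: int
    seed: int


def _check_values(values: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if np.ptp(v) == 0:
        raise ValueError("constant field: autocorrelation undefined")
    return v


def _moran_stat(c: np.ndarray, w, s0: float) -> float:
    # I = (n / S0) * (c' W c) / (c' c) with c the centred values
    return float(len(c) / s0 * (c @ (w @ c)) / (c @ c))


def global_morans_i(values, W: WeightsMatrix, n_perm: int = 999,
                    seed: int | None = None,
                    analytical_z: bool = False) -> MoranResult:
    """Global Moran's I with conditional randomization.

    The z-score is taken from the permutation distribution (mean/sd of
    permuted statistics); ``analytical_z`` switches to the
    normal-approximation moments instead.
    """
    n = W.graph.n
    v = _check_values(values, n)
    c = v - v.mean()
    w, s0 = W.matrix, W.s0
    obs = _moran_stat(c, w, s0)
    e_i = -1.0 / (n - 1)
    if seed is None:
        raise ValueError("seed is required for permutation inference")
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        cp = c[rng.permutation(n)]
        perms[k] = _moran_stat(cp, w, s0)
    p = (1 + np.count_nonzero(np.abs(perms) >= abs(obs))) / (n_perm + 1)
    if analytical_z:
        z = (obs - e_i) / _moran_analytic_sd(W)
    else:
        z = (obs - perms.mean()) / perms.std(ddof=1)
    return MoranResult(obs, e_i, float(z), float(p), n_perm, seed)


def _moran_analytic_sd(W: WeightsMatrix) -> float:
    """Normal-approximation sd of Moran's I under randomization."""
    w = W.matrix.toarray()
    n = w.shape[0]
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    e_i2 = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0)
    return float(np.sqrt(e_i2 - e_i ** 2))


def lisa(values, W: WeightsMatrix, n_perm: int = 999, alpha: float = 0.05,
         seed: int | None = None, fdr: bool = False) -> LISAResult:
    """Local Moran I_i with conditional permutation and quadrant typing.

    ``I_i = (c_i / m2) * sum_j w_ij c_j`` with ``m2 = sum c^2 / n``.
    Region i's own value is held fixed while the others are permuted.
    Categories: HH/LL (clusters), HL/LH (outliers) when significant at
    ``alpha`` (optionally Benjamini-Hochberg adjusted), else NS.
    """
    n = W.graph.n
    v = _check_values(values, n)
    if seed is None:
        raise ValueError("seed is required for permutation inference")
    c = v - v.mean()
    m2 = (c @ c) / n
    w = W.matrix
    lag = w @ c
    local = c * lag / m2
    rng = np.random.default_rng(seed)
    p = np.ones(n)
    lil = w.tolil()
    for i in range(n):
        wi = np.asarray(lil.data[i], dtype=float)
        k = len(wi)
        if k == 0:
            p[i] = 1.0  # island: zero lag, never significant
            continue
        others = np.delete(c, i)
        # draw n_perm neighbour sets without replacement
        picks = np.argpartition(
            rng.random((n_perm, others.size)), k - 1, axis=1)[:, :k]
        perm_lag = (others[picks] * wi).sum(axis=1)
        perm_stat = c[i] * perm_lag / m2
        p[i] = (1 + np.count_nonzero(np.abs(perm_stat) >= abs(local[i]))) \
            / (n_perm + 1)
    if fdr:
        from statsmodels.stats.multitest import multipletests
        sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = p < alpha
    cats = []
    for i in range(n):
        if not sig[i] or alpha <= 0:
            cats.append("NS")
        elif c[i] >= 0 and lag[i] >= 0:
            cats.append("HH")
        elif c[i] < 0 and lag[i] < 0:
            cats.append("LL")
        elif c[i] >= 0:
            cats.append("HL")
        else:
            cats.append("LH")
    if alpha <= 0:
        cats = ["NS"] * n
    return LISAResult(local, p, tuple(cats), alpha, n_perm, seed)


def gi_star(values, graph: RegionGraph) -> GiStarResult:
    """Getis-Ord Gi* with binary weights and self-inclusion (w_ii = 1).

    The statistic is already a z-score; two-sided p-values come from
    the standard normal, binned at the 90/95/99% thresholds.
    """
    n = graph.n
    if n < 3:
        raise ValueError("Gi* needs at least 3 regions")
    x = _check_values(values, n)
    w = graph.adjacency_matrix().toarray() + np.eye(n)
    xbar = x.mean()
    s = np.sqrt((x ** 2).mean() - xbar ** 2)
    wsum = w.sum(axis=1)
    w2sum = (w ** 2).sum(axis=1)
    num = w @ x - xbar * wsum
    den = s * np.sqrt((n * w2sum - wsum ** 2) / (n - 1))
    z = num / den
    p = 2 * sps.norm.sf(np.abs(z))
    bins = []
    for zi in z:
        a = abs(zi)
        if a >= _Z99:
            bins.append("hot99" if zi > 0 else "cold99")
        elif a >= _Z95:
            bins.append("hot95" if zi > 0 else "cold95")
        elif a >= _Z90:
            bins.append("hot90" if zi > 0 else "cold90")
        else:
            bins.append("NS")
    return GiStarResult(z, p, tuple(bins))


def st_morans_i(panel_values, stw: STWeights, n_perm: int = 999,
                seed: int | None = None) -> STMoranResult:
    """Spatiotemporal Moran's I over joint (region, year) cells.

    ``panel_values`` is an (n, T) array in the graph's region order and
    the STWeights' year order.  Inference permutes space-time cells
    jointly.  With T = 1 this equals global Moran's I on the spatial
    binary weights.
    """
    n, big_t = stw.graph.n, len(stw.years)
    y = np.asarray(panel_values, dtype=float)
    if y.shape != (n, big_t):
        raise ValueError(f"expected balanced panel of shape {(n, big_t)}, "
                         f"got {y.shape}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("constant panel: autocorrelation undefined")
    if seed is None:
        raise ValueError("seed is required for permutation inference")
    c = (y - y.mean()).ravel()  # cell order (i, t) -> i*T + t
    w, s0 = stw.matrix, stw.s0
    obs = _moran_stat(c, w, s0)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        cp = c[rng.permutation(c.size)]
        perms[k] = _moran_stat(cp, w, s0)
    p = (1 + np.count_nonzero(np.abs(perms) >= abs(obs))) / (n_perm + 1)
    z = (obs - perms.mean()) / perms.std(ddof=1)
    return STMoranResult(obs, float(z), float(p), n, big_t, stw.scheme,
                         n_perm, seed)
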
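"""Surface extraction, entropic optimal-transport comparison and the
collimator-differentiability statistics.

Segmented shells are turned into point clouds with marching cubes; each
pair of clouds is compared with the debiased entropic OT (Sinkhorn)
divergence

    S_eps(a, b) = OT_eps(a, b) - (OT_eps(a, a) + OT_eps(b, b)) / 2
                  + eps/2 (m(a) - m(b))^2,

squared-Euclidean ground cost, uniform weights.  ``rho`` soft-penalizes
the marginal constraints (KL penalty) for unbalanced comparison of
clouds with different point counts; ``rho = None`` is the balanced
limit.  Clouds are centered and scaled to unit RMS radius first, so the
default blur eps = 1e-3 is on a comparable scale for every pair.  The
solver is a log-domain Sinkhorn with eps-annealing.

Per collimation geometry, the upper triangle of the pairwise distance
matrix feeds a one-sample Wilcoxon signed-rank test of median zero
(exact null by rank-sum enumeration up to n = 25, normal approximation
with tie correction beyond).  Because all pairwise distances are
positive, this literal test is trivially significant at large n; the
median distance is therefore reported alongside as the effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_grid_io import BinaryMask

__all__ = [
    "SurfaceCloud",
    "SinkhornConfig",
    "extract_surface",
    "sinkhorn_distance",
    "pairwise_matrix",
    "wilcoxon_one_sample",
    "geometry_significance",
    "export_parameter_table",
    "umap_embed",
]


@dataclass
class SurfaceCloud:
    """Point cloud (mm) with optional non-negative per-point weights."""

    points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        P = np.asarray(self.points, dtype=np.float64)
        if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
            raise ValueError("need an (n >= 4, 3) coordinate array")
        if not np.all(np.isfinite(P)):
            raise ValueError("coordinates must be finite")
        self.points = P
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (P.shape[0],) or w.min() < 0:
                raise ValueError("weights must be non-negative, one per point")
            self.weights = w

    def normalized(self) -> np.ndarray:
        """Points centered and scaled to unit RMS radius."""
        P = self.points - self.points.mean(axis=0)
        rms = np.sqrt(np.mean(np.sum(P**2, axis=1)))
        return P / rms if rms > 0 else P


@dataclass
class SinkhornConfig:
    blur: float = 1e-3            # entropic regularization eps
    rho: float | None = 1.0       # KL marginal penalty; None = balanced
    max_iter: int = 200
    tol: float = 1e-2
    normalize: bool = True        # center/scale clouds before OT
    max_points: int = 512         # deterministic subsample cap per cloud

    def __post_init__(self):
        if self.blur <= 0:
            raise ValueError("blur must be > 0")


class SinkhornError(RuntimeError):
    """Sinkhorn iterations failed to converge."""


def extract_surface(mask: BinaryMask, spacing=None) -> SurfaceCloud:
    """Marching-cubes vertices of the 0.5 isolevel of a binary mask (mm)."""
    from skimage.measure import marching_cubes

    n = int(mask.mask.sum())
    if n == 0 or n == mask.mask.size:
        raise ValueError("mask must contain both classes")
    sp = tuple(spacing) if spacing is not None else mask.spacing
    verts, *_ = marching_cubes(mask.mask.astype(np.float64), level=0.5, spacing=sp)
    return SurfaceCloud(verts)


def _softmin(M: np.ndarray, eps: float, axis: int, logw: np.ndarray) -> np.ndarray:
    """-eps * logsumexp(logw - M/eps) along axis."""
    from scipy.special import logsumexp

    shape = [1, 1]
    shape[axis] = -1
    return -eps * logsumexp(logw.reshape(shape) - M / eps, axis=axis)


def _ot_cost(X: np.ndarray, Y: np.ndarray, a: np.ndarray, b: np.ndarray,
             cfg: SinkhornConfig) -> float:
    """Entropic OT cost between weighted clouds via log-domain Sinkhorn.

    Anneals eps from a coarse value down to cfg.blur so the small target
    blur converges in few iterations.
    """
    M = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(M, 0.0, out=M)
    la, lb = np.log(a), np.log(b)
    f = np.zeros(len(a))
    g = np.zeros(len(b))
    eps_list = []
    e = max(float(M.max()), cfg.blur)
    while e > cfg.blur:
        eps_list.append(e)
        e /= 2.0
    eps_list.append(cfg.blur)

    unb = cfg.rho is not None and np.isfinite(cfg.rho)
    for eps in eps_list:
        scale = cfg.rho / (cfg.rho + eps) if unb else 1.0
        last = eps == cfg.blur
        # potential updates shrink with eps near the fixed point, so the
        # stopping rule is scaled by eps (geomloss-style annealed schedule)
        thresh = cfg.tol * max(eps, 1e-12)
        update = np.inf
        for it in range(cfg.max_iter if last else 10):
            # simultaneous (Jacobi) updates keep the iteration exactly
            # symmetric under swapping the two clouds
            f_new = scale * _softmin(M - g[None, :], eps, axis=1, logw=lb)
            g_new = scale * _softmin((M - f[:, None]), eps, axis=0, logw=la)
            update = float(max(np.max(np.abs(f_new - f)),
                               np.max(np.abs(g_new - g))))
            f, g = 0.5 * (f + f_new), 0.5 * (g + g_new)
            if last and update < thresh:
                break
        # accept a small residual drift (the unbalanced fixed point is
        # approached at rate rho/(rho+eps)); only a genuinely unconverged
        # or non-finite state is an error
        if last and (not np.isfinite(update)
                     or update > 0.01 * (1 + float(np.max(np.abs(f))))):
            raise SinkhornError(
                f"no convergence in {cfg.max_iter} iterations at eps={eps}; "
                f"final update {update:.3e}"
            )
    # primal transport cost <pi, M> with pi from the final potentials
    logpi = (
        la[:, None] + lb[None, :] + (f[:, None] + g[None, :] - M) / cfg.blur
    )
    pi = np.exp(logpi)
    return float(np.sum(pi * M))


def sinkhorn_distance(A: SurfaceCloud, B: SurfaceCloud,
                      cfg: SinkhornConfig | None = None) -> float:
    """Debiased Sinkhorn divergence between two surface clouds (>= 0)."""
    cfg = cfg or SinkhornConfig()
    X = A.normalized() if cfg.normalize else A.points
    Y = B.normalized() if cfg.normalize else B.points
    a = (A.weights / A.weights.sum()) if A.weights is not None else (
        np.full(len(X), 1.0 / len(X))
    )
    b = (B.weights / B.weights.sum()) if B.weights is not None else (
        np.full(len(Y), 1.0 / len(Y))
    )
    # cap cloud size with a deterministic stride subsample (weights renormalized)
    if cfg.max_points and len(X) > cfg.max_points:
        sel = np.linspace(0, len(X) - 1, cfg.max_points).astype(int)
        X, a = X[sel], a[sel] / a[sel].sum()
    if cfg.max_points and len(Y) > cfg.max_points:
        sel = np.linspace(0, len(Y) - 1, cfg.max_points).astype(int)
        Y, b = Y[sel], b[sel] / b[sel].sum()
    ab = _ot_cost(X, Y, a, b, cfg)
    aa = _ot_cost(X, X, a, a, cfg)
    bb = _ot_cost(Y, Y, b, b, cfg)
    d = ab - 0.5 * (aa + bb) + 0.5 * cfg.blur * (a.sum() - b.sum()) ** 2
    return float(d)


def pairwise_matrix(clouds: list, cfg: SinkhornConfig | None = None) -> np.ndarray:
    """Symmetric Sinkhorn-divergence matrix with (near-)zero diagonal."""
    if len(clouds) < 2:
        raise ValueError("need at least 2 clouds")
    n = len(clouds)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sinkhorn_distance(clouds[i], clouds[j], cfg)
    return D


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, one-sample
# ---------------------------------------------------------------------------

def _signed_ranks(values: np.ndarray):
    """Midranks of |values| after dropping zeros."""
    from scipy.stats import rankdata

    v = np.asarray(values, dtype=np.float64)
    v = v[v != 0]
    if v.size == 0:
        raise ValueError("all values are zero; signed-rank test degenerate")
    ranks = rankdata(np.abs(v))
    return v, ranks


def _exact_two_sided_p(w_obs: float, ranks: np.ndarray) -> float:
    """Exact null by dynamic programming over the 2^n sign patterns.

    Midranks are multiples of 1/2, so the DP runs on doubled integer
    ranks; equivalent to full enumeration but feasible for n <= 25.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_obs))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_two_sided_p(w_obs: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
    if var <= 0:
        return 1.0
    # standard continuity correction
    z = (abs(w_obs - mean) - 0.5) / math.sqrt(var)
    from scipy.stats import norm

    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def wilcoxon_one_sample(values, exact_limit: int = 25):
    """One-sample Wilcoxon signed-rank test of median zero, two-sided.

    Zeros are dropped, absolute values midranked; W is the sum of
    positively signed ranks.  The p-value is exact (sign-pattern
    enumeration) for n <= exact_limit, else a tie-corrected normal
    approximation.  Returns (W, p).
    """
    v, ranks = _signed_ranks(np.asarray(values, dtype=np.float64))
    w = float(ranks[v > 0].sum())
    if len(v) <= exact_limit:
        p = _exact_two_sided_p(w, ranks)
    else:
        p = _normal_two_sided_p(w, ranks)
    return w, p


def geometry_significance(groups: dict, cfg: SinkhornConfig | None = None) -> dict:
    """Per-geometry Wilcoxon test on the upper-triangular Sinkhorn matrix.

    ``groups`` maps a geometry name to a list of >= 3 masks (or
    pre-extracted SurfaceClouds).  Returns
    {name: {statistic, p, median_distance, n_pairs}}; an all-zero
    distance matrix (identical shapes) is reported as degenerate with
    p = None.
    """
    out = {}
    for name, members in groups.items():
        if len(members) < 3:
            raise ValueError(f"group '{name}' needs >= 3 masks")
        clouds = [
            m if isinstance(m, SurfaceCloud) else extract_surface(m)
            for m in members
        ]
        D = pairwise_matrix(clouds, cfg)
        tri = D[np.triu_indices(len(clouds), k=1)]
        entry = {
            "n_pairs": tri.size,
            "median_distance": float(np.median(tri)),
        }
        if np.all(tri == 0):
            entry.update(statistic=None, p=None, degenerate=True)
        else:
            w, p = wilcoxon_one_sample(tri)
            entry.update(statistic=w, p=p, degenerate=False)
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# Parameter export for external embedding
# ---------------------------------------------------------------------------

def export_parameter_table(masks: list, labels: list, path: str,
                           grid=None, **fit_kwargs) -> None:
    """Fit LV parameters to each mask and write a CSV for any external
    embedder (one row per mask: label, a, b, c, d, kappa, sigma, residual)."""
    from .lv_model import fit_params_to_mask

    with open(path, "w", encoding="ascii") as fh:
        fh.write("label,a,b,c,d,kappa,sigma,residual_mm\n")
        for mask, label in zip(masks, labels):
            p, _, res = fit_params_to_mask(mask, grid=grid, **fit_kwargs)
            fh.write(
                f"{label},{p.a:.6g},{p.b:.6g},{p.c:.6g},{p.d:.6g},"
                f"{p.kappa:.6g},{p.sigma:.6g},{res:.6g}\n"
            )


def umap_embed(features: np.ndarray, **kwargs) -> np.ndarray:
    """Thin wrapper over an external UMAP embedder (optional dependency)."""
    try:
        import umap
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "umap-learn is not installed; install the 'umap' extra"
        ) from exc
    return umap.UMAP(**kwargs).fit_transform(np.asarray(features))
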
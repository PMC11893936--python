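"""Nonlinear statistical shape prior in kernel feature space.

Shapes are fixed-length descriptors z (by default the 6-vector of LV
model parameters, z-scored per coordinate).  The prior is the negative
log of a Gaussian fitted in a kernel-induced feature space: a
Mahalanobis-type energy

    E(z) = phi~(z)^T  Sigma_phi^{-1}  phi~(z),

where phi~ is the feature map centered on the training mean and the
feature covariance's null directions (inevitable with m samples in a
high-dimensional feature space) are regularized by replacing their zero
eigenvalues with a constant lambda_perp:

    Sigma_phi = V Lambda V^T + lambda_perp (I - V V^T).

Since the eigenvectors V_k lie in the span of the mapped training data,
everything reduces to the doubly centered kernel matrix: with centered
kernel k~ and kernel-matrix eigenpairs, the energy evaluates as

    E(z) = sum_k ( sum_i alpha_i^k k~(z_i, z) )^2 (1/lambda_k - 1/lambda_perp)
           + k~(z, z) / lambda_perp.

A linear kernel makes the feature space explicit, which the tests use
as the module's correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lv_model import LVParams, Pose, PriorVolume, rasterize_prior

__all__ = [
    "PriorTrainingSet",
    "KernelPriorModel",
    "TrainingError",
    "linear_kernel",
    "rbf_kernel",
    "train_prior",
    "prior_energy",
    "preferred_shapes_to_prior_image",
    "center_descriptor",
    "descriptor_from_params",
    "default_prior_bank",
]


class TrainingError(ValueError):
    """Degenerate or rank-deficient training configuration."""


def linear_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return X @ Y.T


def rbf_kernel(X: np.ndarray, Y: np.ndarray, h: float) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * h**2))


@dataclass
class PriorTrainingSet:
    """m shape descriptors of common length n (m >= 2)."""

    shapes: np.ndarray

    def __post_init__(self):
        Z = np.asarray(self.shapes, dtype=np.float64)
        if Z.ndim != 2 or Z.shape[0] < 2:
            raise TrainingError("need an (m, n) array with m >= 2 shapes")
        if not np.all(np.isfinite(Z)):
            raise TrainingError("descriptors must be finite")
        self.shapes = Z

    @property
    def m(self) -> int:
        return self.shapes.shape[0]


@dataclass
class KernelPriorModel:
    """Trained kernel-space shape statistics."""

    Z: np.ndarray                  # training descriptors, (m, n)
    kernel: str                    # 'rbf' or 'linear'
    bandwidth: float               # RBF bandwidth h (ignored for linear)
    alpha: np.ndarray              # (m, r) coefficients alpha_i^k
    eigvals: np.ndarray            # lambda_1 >= ... >= lambda_r > 0
    lambda_perp: float
    K_train: np.ndarray = field(repr=False, default=None)
    row_means: np.ndarray = field(repr=False, default=None)
    grand_mean: float = 0.0

    def _k(self, X, Y):
        if self.kernel == "linear":
            return linear_kernel(X, Y)
        return rbf_kernel(X, Y, self.bandwidth)


def _median_heuristic(Z: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    d = pdist(Z)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return med if med > 0 else 1.0


def train_prior(ts: PriorTrainingSet, kernel: str = "rbf",
                lambda_perp: float | None = None, r: int | None = None,
                bandwidth: float | None = None) -> KernelPriorModel:
    """Fit the kernel-space Gaussian: centered kernel eigenpairs and
    span coefficients normalized so the feature-space eigenvectors have
    unit norm.  Deterministic: symmetric eigensolver, eigenvalues
    descending, sign fixed by making each eigenvector's first nonzero
    coefficient positive."""
    Z = ts.shapes
    m = Z.shape[0]
    r = r if r is not None else m - 1
    if not 1 <= r <= m - 1:
        raise TrainingError(f"need 1 <= r <= m-1 = {m - 1}, got r={r}")
    if kernel not in ("rbf", "linear"):
        raise TrainingError(f"unknown kernel '{kernel}'")
    h = bandwidth if bandwidth is not None else (
        _median_heuristic(Z) if kernel == "rbf" else 1.0
    )
    K = linear_kernel(Z, Z) if kernel == "linear" else rbf_kernel(Z, Z, h)
    H = np.eye(m) - np.full((m, m), 1.0 / m)
    Kc = H @ K @ H
    mu, E = np.linalg.eigh(Kc)          # ascending
    mu, E = mu[::-1], E[:, ::-1]
    tol = max(mu[0], 0.0) * m * 1e-12 + 1e-300
    if mu[r - 1] <= tol:
        raise TrainingError(
            f"centered kernel matrix has rank < r={r}; reduce r or perturb data"
        )
    mu_r = mu[:r]
    # feature covariance (1/m) sum phi~ phi~^T has eigenvalues mu/m;
    # V_k = sum_i alpha_i^k phi~(z_i) with alpha^k = e_k / sqrt(mu_k) (unit V_k)
    alpha = E[:, :r] / np.sqrt(mu_r)[None, :]
    for k in range(r):
        col = alpha[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-14)
        if nz.size and col[nz[0]] < 0:
            alpha[:, k] = -col
    eigvals = mu_r / m
    lp = lambda_perp if lambda_perp is not None else eigvals[-1] / 2.0
    if lp <= 0:
        raise TrainingError("lambda_perp must be > 0")
    return KernelPriorModel(
        Z=Z.copy(),
        kernel=kernel,
        bandwidth=h,
        alpha=alpha,
        eigvals=eigvals,
        lambda_perp=float(lp),
        K_train=K,
        row_means=K.mean(axis=1),
        grand_mean=float(K.mean()),
    )


def _centered_cross(model: KernelPriorModel, z: np.ndarray):
    """k~(z_i, z) vector and k~(z, z) for one query descriptor."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    kz = model._k(model.Z, z)[:, 0]                 # k(z_i, z)
    kzz = float(model._k(z, z)[0, 0])
    kt = kz - model.row_means - kz.mean() + model.grand_mean
    ktt = kzz - 2.0 * kz.mean() + model.grand_mean
    return kt, ktt


def prior_energy(model: KernelPriorModel, z) -> float:
    """Regularized kernel-Mahalanobis energy of a shape descriptor (>= 0)."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != model.Z.shape[1]:
        raise TrainingError(
            f"descriptor length {z.shape[-1]} != training length {model.Z.shape[1]}"
        )
    kt, ktt = _centered_cross(model, z)
    proj = model.alpha.T @ kt                        # <V_k, phi~(z)>
    e = float(
        np.sum(proj**2 * (1.0 / model.eigvals - 1.0 / model.lambda_perp))
        + ktt / model.lambda_perp
    )
    return max(e, 0.0)


def center_descriptor(z) -> np.ndarray:
    """Remove the descriptor's own mean (z -> z - mean(z) 1).

    Feeding centered descriptors to the prior makes the energy invariant
    to a global translation of the descriptor vector, the normalization
    that renders the statistics pose-insensitive."""
    z = np.asarray(z, dtype=np.float64)
    return z - z.mean()


def descriptor_from_params(p: LVParams, mean: np.ndarray | None = None,
                           std: np.ndarray | None = None) -> np.ndarray:
    """Default shape descriptor: the 6 LV parameters, optionally z-scored."""
    v = p.as_vector()
    if mean is not None:
        v = (v - np.asarray(mean)) / np.where(np.asarray(std) > 0, std, 1.0)
    return v


def preferred_shapes_to_prior_image(model: KernelPriorModel,
                                    candidates: list, pose: Pose,
                                    grid, temperature: float = 1.0,
                                    descriptors: np.ndarray | None = None,
                                    soft_edge: float = 1.0) -> PriorVolume:
    """Energy-weighted blend of candidate shells into one prior image.

    Weights are softmax(-E(z_j)/temperature); in the temperature -> 0
    limit the minimum-energy candidate alone survives.  If every weight
    underflows, uniform weights are used with a warning.
    """
    if not candidates:
        raise ValueError("need at least one candidate shape")
    if descriptors is None:
        descriptors = np.array([descriptor_from_params(p) for p in candidates])
    E = np.array([prior_energy(model, d) for d in descriptors])
    t = max(float(temperature), 1e-300)
    logw = -(E - E.min()) / t
    w = np.exp(logw)
    s = w.sum()
    if not np.isfinite(s) or s <= 0:
        import warnings

        warnings.warn("prior weights underflowed; falling back to uniform")
        w = np.ones(len(candidates))
        s = w.sum()
    w = w / s
    # candidates contributing < 0.1% of the blend are not rasterized
    keep = w >= 1e-3
    w = np.where(keep, w, 0.0)
    w = w / w.sum()
    acc = None
    for wj, pj in zip(w, candidates):
        if wj == 0.0:
            continue
        pri = rasterize_prior(pj, pose, grid, soft_edge=soft_edge)
        acc = wj * pri.vol.data if acc is None else acc + wj * pri.vol.data
    return PriorVolume(grid.like(np.clip(acc, 0.0, 1.0)))


def default_prior_bank(counts: dict | None = None):
    """Candidate LV shapes on the anatomical parameter grid plus a kernel
    prior trained on their z-scored descriptors.

    Returns ``(candidates, model)``; the default grid of 20 shapes spans
    the adult-LV bounds of :data:`cmflv.lv_model.DEFAULT_BOUNDS`.
    """
    from .lv_model import sample_parameter_grid

    candidates = sample_parameter_grid(
        counts=counts or {"a": 3, "b": 2, "c": 3, "d": 2}
    )
    Z = np.array([descriptor_from_params(p) for p in candidates])
    std = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    Zs = (Z - Z.mean(axis=0)) / std
    model = train_prior(PriorTrainingSet(Zs))
    return candidates, model
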
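"""Low-parameter left-ventricle shape model.

The myocardial shell is described by two half-ellipse profile curves in
the (axis, radius) half-plane, rotated about the x axis:

    c_epi(u)  = a * sqrt(1 - u^2 / c^2),   u in [sigma, c]   (outer wall)
    c_endo(v) = b * sqrt(1 - v^2 / d^2),   v in [sigma, d]   (cavity wall)

with ``a > b`` the radial scales, ``c > d`` the half-lengths, and
``sigma`` the basal truncation abscissa.  The apex points toward +x, the
truncated base toward -x.  The open base is closed by a septal/basal cap
curve running between the epicardial and endocardial basal endpoints
(radii r_epi = c_epi(sigma), r_endo = c_endo(sigma)); its bulge toward
-x follows the reciprocal curvature family: the amplitude is the band
minimum ``4 / (kappa * (r_epi - r_endo)^2)`` of
``1/(kappa (r_epi - w)(w - r_endo))`` (kappa in 1/mm^2, offsets in mm),
carried by a parabolic profile that vanishes at both endpoints so the
cap meets the two walls exactly; larger kappa flattens the base.

Six scalars (a, b, c, d, kappa, sigma) plus a similarity pose therefore
span the whole family of shell shapes the prior is trained on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core_grid_io import BinaryMask, Volume

__all__ = [
    "LVParams",
    "Pose",
    "PriorVolume",
    "ParameterError",
    "profile_curves",
    "rasterize_prior",
    "sample_parameter_grid",
    "estimate_pose",
    "fit_params_to_mask",
    "DEFAULT_BOUNDS",
]


class ParameterError(ValueError):
    """LV shape parameters violate the model's geometric invariants."""


@dataclass(frozen=True)
class LVParams:
    """Shape parameters in mm (kappa in 1/mm^2).

    Defaults approximate an adult LV: outer radius 35 mm, outer
    base-to-apex length ~80 mm, wall thickness ~10 mm.
    """

    a: float = 35.0
    b: float = 25.0
    c: float = 85.0
    d: float = 75.0
    kappa: float = 0.008
    sigma: float = 5.0

    def __post_init__(self):
        if not (self.a > self.b > 0):
            raise ParameterError(f"need a > b > 0, got a={self.a}, b={self.b}")
        if not (self.c > self.d > 0):
            raise ParameterError(f"need c > d > 0, got c={self.c}, d={self.d}")
        if not (0 <= self.sigma < self.d):
            raise ParameterError(f"need 0 <= sigma < d, got sigma={self.sigma}")
        if not self.kappa > 0:
            raise ParameterError(f"need kappa > 0, got {self.kappa}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.kappa, self.sigma])

    @classmethod
    def from_vector(cls, v) -> "LVParams":
        return cls(*(float(x) for x in v))


DEFAULT_BOUNDS = {
    "a": (28.0, 45.0),
    "b": (18.0, 34.0),
    "c": (65.0, 100.0),
    "d": (55.0, 90.0),
    "kappa": (0.004, 0.02),
    "sigma": (0.0, 15.0),
}


@dataclass
class Pose:
    """Similarity transform: world = R (scale * local) + translation."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: Rotation = field(default_factory=Rotation.identity)
    scale: float = 1.0

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.scale <= 0:
            raise ParameterError("pose scale must be > 0")

    def world_to_local(self, pts: np.ndarray) -> np.ndarray:
        return self.rotation.inv().apply(pts - self.translation) / self.scale


@dataclass
class PriorVolume:
    """Soft myocardium membership in [0, 1] on a voxel grid."""

    vol: Volume

    def __post_init__(self):
        v = self.vol.data
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ParameterError("prior membership must lie in [0, 1]")
        np.clip(v, 0.0, 1.0, out=v)


def epi_radius(p: LVParams, u) -> np.ndarray:
    """Epicardial profile radius a*sqrt(1 - u^2/c^2) (0 outside |u| <= c)."""
    u = np.asarray(u, dtype=np.float64)
    r2 = 1.0 - u**2 / p.c**2
    return p.a * np.sqrt(np.maximum(r2, 0.0))


def endo_radius(p: LVParams, v) -> np.ndarray:
    """Endocardial profile radius b*sqrt(1 - v^2/d^2) (0 outside |v| <= d)."""
    v = np.asarray(v, dtype=np.float64)
    r2 = 1.0 - v**2 / p.d**2
    return p.b * np.sqrt(np.maximum(r2, 0.0))


def _cap_offset(p: LVParams, r) -> np.ndarray:
    """Basal cap bulge toward -x as a function of radius (0 outside the band)."""
    r = np.asarray(r, dtype=np.float64)
    r_epi = float(epi_radius(p, p.sigma))
    r_endo = float(endo_radius(p, p.sigma))
    width = r_epi - r_endo
    if width <= 0:
        return np.zeros_like(r)
    amp = 4.0 / (p.kappa * width**2)          # band minimum of the reciprocal family
    quad = (r_epi - r) * (r - r_endo)
    return np.where(quad > 0, amp * 4.0 * quad / width**2, 0.0)


def profile_curves(p: LVParams, n: int = 100) -> dict:
    """Sampled epicardial, endocardial and septal (basal cap) curves.

    Returns a dict of (abscissa, radius) sample arrays: ``epi`` on
    [sigma, c], ``endo`` on [sigma, d], and ``septal`` running from the
    epicardial basal endpoint to the endocardial one.
    """
    if n < 2:
        raise ParameterError("need n >= 2 samples")
    u = np.linspace(p.sigma, p.c, n)
    v = np.linspace(p.sigma, p.d, n)
    w = np.linspace(float(epi_radius(p, p.sigma)), float(endo_radius(p, p.sigma)), n)
    return {
        "epi": (u, epi_radius(p, u)),
        "endo": (v, endo_radius(p, v)),
        "septal": (p.sigma - _cap_offset(p, w), w),
    }


def _shell_membership(p: LVParams, x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Hard in-shell indicator at local axial coordinate x and radius r."""
    inside_epi = (np.abs(x) <= p.c) & (r <= epi_radius(p, x))
    in_cavity = (np.abs(x) <= p.d) & (r < endo_radius(p, x))
    above_base = x >= p.sigma - _cap_offset(p, r)
    return inside_epi & ~in_cavity & above_base


def rasterize_prior(p: LVParams, pose: Pose | None = None,
                    grid: Volume | None = None, soft_edge: float = 1.0) -> PriorVolume:
    """Voxelize the myocardial shell onto a grid.

    ``soft_edge`` is the Gaussian smoothing width in voxels (0 for a hard
    binary shell); softening reduces aliasing in the prior image.
    """
    if grid is None:
        grid = default_grid()
    pose = pose or Pose()
    nx, ny, nz = grid.shape
    sp = grid.spacing
    ax = [grid.origin[i] + sp[i] * np.arange(grid.shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    local = pose.world_to_local(pts)
    xl = local[:, 0].reshape(grid.shape)
    rl = np.hypot(local[:, 1], local[:, 2]).reshape(grid.shape)
    shell = _shell_membership(p, xl, rl).astype(np.float64)
    if not shell.any():
        import warnings

        warnings.warn("LV shell lies entirely outside the grid; prior is empty")
    if soft_edge > 0:
        from scipy.ndimage import gaussian_filter

        shell = gaussian_filter(shell, sigma=soft_edge)
        m = shell.max()
        if m > 0:
            shell = np.clip(shell / m, 0.0, 1.0)
    return PriorVolume(grid.like(shell))


def default_grid(n: int = 64, spacing: float = 4.8) -> Volume:
    """Centered n^3 grid at isotropic spacing (mm), origin so 0 is the center."""
    half = spacing * (n - 1) / 2.0
    return Volume(np.zeros((n, n, n)), (spacing,) * 3, (-half, -half, -half))


def sample_parameter_grid(bounds: dict | None = None,
                          counts: dict | None = None) -> list:
    """Cartesian uniform grid over the parameter box, filtered to valid sets.

    ``counts`` of 1 for a field picks the interval midpoint.
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    counts = {k: 1 for k in bounds} | (counts or {})
    axes = {}
    for k, (lo, hi) in bounds.items():
        nk = int(counts[k])
        if nk < 1:
            raise ParameterError(f"count for {k} must be >= 1")
        axes[k] = np.linspace(lo, hi, nk) if nk > 1 else np.array([(lo + hi) / 2])
    names = ["a", "b", "c", "d", "kappa", "sigma"]
    out = []
    for combo in itertools.product(*(axes[k] for k in names)):
        try:
            out.append(LVParams(*(float(v) for v in combo)))
        except ParameterError:
            continue
    if not out:
        raise ParameterError("no valid parameter sets in the given box")
    return out


# ---------------------------------------------------------------------------
# Pose estimation and parameter fitting
# ---------------------------------------------------------------------------

def _mask_surface_points(mask: BinaryMask) -> np.ndarray:
    from skimage.measure import marching_cubes

    if not (0 < mask.mask.sum() < mask.mask.size):
        raise ParameterError("mask must contain both classes")
    verts, *_ = marching_cubes(mask.mask.astype(np.float64), level=0.5,
                               spacing=mask.spacing)
    return verts


def _mask_centroid(mask: BinaryMask, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    idx = np.argwhere(mask.mask > 0)
    return np.asarray(origin) + idx.mean(axis=0) * np.asarray(mask.spacing)


def estimate_pose(mask: BinaryMask, params: LVParams,
                  grid: Volume | None = None) -> Pose:
    """Centroid + principal-axes similarity pose of the shell in a mask.

    The first principal axis of the foreground voxels becomes the model
    x axis; the axis sign (apex direction) is resolved by rasterizing
    both orientations and keeping the better-overlapping one.
    """
    grid = grid if grid is not None else Volume(
        np.zeros(mask.shape), mask.spacing
    )
    idx = np.argwhere(mask.mask > 0).astype(np.float64)
    if idx.shape[0] < 4:
        raise ParameterError("mask too small for pose estimation")
    pts = np.asarray(grid.origin) + idx * np.asarray(mask.spacing)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]

    best = None
    for sign in (1.0, -1.0):
        v = sign * axis
        rot, _ = Rotation.align_vectors(
            np.array([v, [0.0, 0.0, 1.0]]),
            np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
            weights=[1.0, 1e-6],
        )
        # start at the mask centroid, then shift so the shell centroid lands there
        pose = _recenter_pose(
            params, Pose(translation=centroid, rotation=rot), centroid, grid
        )
        pri = rasterize_prior(params, pose, grid, soft_edge=0.0)
        inter = float(np.sum((pri.vol.data > 0.5) & (mask.mask > 0)))
        if best is None or inter > best[0]:
            best = (inter, pose)
    return best[1]


def _recenter_pose(params: LVParams, pose: Pose, target: np.ndarray,
                   grid: Volume) -> Pose:
    """Shift the pose translation so the rasterized shell centroid hits target."""
    pri = rasterize_prior(params, pose, grid, soft_edge=0.0)
    m = pri.vol.data > 0.5
    if not m.any():
        return pose
    idx = np.argwhere(m).astype(np.float64)
    com = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    return Pose(
        translation=pose.translation + (target - com.mean(axis=0)),
        rotation=pose.rotation,
        scale=pose.scale,
    )


def _surface_residual(params: LVParams, pose: Pose, grid: Volume,
                      mask_pts: np.ndarray, mask_tree: cKDTree) -> float:
    pri = rasterize_prior(params, pose, grid, soft_edge=0.0)
    m = pri.vol.data > 0.5
    if not (0 < m.sum() < m.size):
        return float("inf")
    model_pts = _mask_surface_points(BinaryMask(m.astype(np.uint8), grid.spacing))
    model_pts = model_pts + np.asarray(grid.origin)
    d_ab = mask_tree.query(model_pts)[0].mean()
    d_ba = cKDTree(model_pts).query(mask_pts)[0].mean()
    return 0.5 * (d_ab + d_ba)


def fit_params_to_mask(mask: BinaryMask, init: LVParams | None = None,
                       pose0: Pose | None = None, grid: Volume | None = None,
                       maxiter: int = 200):
    """Fit shape parameters (a, b, c, d, kappa) to a binary shell mask.

    Minimizes the symmetric mean surface distance (mm) between the
    rasterized model and the mask's marching-cubes surface with a
    Nelder–Mead simplex; pose is pre-aligned by centroid and principal
    axes when not supplied.  Returns ``(params, pose, residual_mm)``;
    on optimizer failure the initial parameters come back with an
    infinite residual.
    """
    init = init or LVParams()
    grid = grid if grid is not None else Volume(np.zeros(mask.shape), mask.spacing)
    if mask.mask.sum() == 0:
        raise ParameterError("empty mask")
    pose = pose0 if pose0 is not None else estimate_pose(mask, init, grid)
    mask_pts = _mask_surface_points(mask) + np.asarray(grid.origin)
    mask_tree = cKDTree(mask_pts)

    x0 = np.array([init.a, init.b, init.c, init.d, init.kappa])
    scales = np.array([10.0, 10.0, 20.0, 20.0, 0.01])

    def unpack(x):
        a, b, c, d, kappa = x0 + x * scales
        return LVParams(a=a, b=b, c=c, d=d, kappa=kappa, sigma=init.sigma)

    def objective(x):
        try:
            p = unpack(x)
        except ParameterError:
            return 1e6
        return _surface_residual(p, pose, grid, mask_pts, mask_tree)

    # the rasterized objective is piecewise constant at the voxel scale, so
    # the initial simplex must straddle several voxels to see any slope
    simplex = np.zeros((6, 5))
    for i in range(5):
        simplex[i + 1, i] = 0.4
    try:
        res = minimize(objective, np.zeros(5), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3,
                                "fatol": 1e-4, "initial_simplex": simplex})
        best = unpack(res.x)
        residual = float(res.fun)
    except Exception:
        return init, pose, float("inf")
    if not np.isfinite(residual):
        return init, pose, float("inf")
    return best, pose, residual
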
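"""Continuous max-flow solver for the convex-relaxed two-phase min-cut.

The relaxed segmentation energy over labels ``lam(x) in [0, 1]`` is

    E(lam) = ∫ (1 - lam) C_s + lam C_t + C |grad lam| dx,

the continuous analogue of a source/sink graph cut: ``C_s``/``C_t`` are
source and sink capacities (cost of labeling a voxel background resp.
foreground) and ``C`` caps the spatial flow, i.e. weights the
total-variation boundary term.  The dual is a max-flow problem with flows
``p_s, p_t, p`` constrained by the capacities and the conservation law
``div p = p_s - p_t``; the label doubles as the Lagrange multiplier of
that constraint.

The solver is the multiplier-based (augmented Lagrangian) algorithm:
each outer iteration maximizes the Lagrangian

    L_c = ∫ p_s + lam (div p - p_s + p_t) dx - (c/2) ||div p - p_s + p_t||²

blockwise over p (a few Chambolle-style projected-gradient steps), then
p_s and p_t (pointwise capped closed forms), then updates the multiplier
lam <- lam - c (div p - p_s + p_t).  Thresholding the converged relaxed
label at almost any t in (0, 1) yields a binary global minimizer
(truncation property), so t = 0.5 is used by default.

Everything is deterministic: fixed initialization, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_grid_io import (
    BinaryMask,
    GridError,
    LabelField,
    VectorField,
    divergence,
    gradient,
)

__all__ = [
    "CapacityField",
    "CMFConfig",
    "FlowState",
    "primal_energy",
    "chambolle_project",
    "threshold_label",
    "solve_cmf",
]


@dataclass
class CapacityField:
    """Source/sink/spatial capacities on one voxel grid.

    ``C`` may be passed as a scalar (the constant TV weight alpha)."""

    Cs: np.ndarray
    Ct: np.ndarray
    C: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.Cs = np.asarray(self.Cs, dtype=np.float64)
        self.Ct = np.asarray(self.Ct, dtype=np.float64)
        if np.isscalar(self.C) or np.ndim(self.C) == 0:
            self.C = np.full(self.Cs.shape, float(self.C))
        self.C = np.asarray(self.C, dtype=np.float64)
        if not (self.Cs.shape == self.Ct.shape == self.C.shape):
            raise GridError("capacity arrays must share one grid")
        for name, a in (("Cs", self.Cs), ("Ct", self.Ct), ("C", self.C)):
            if not np.all(np.isfinite(a)) or a.min() < 0:
                raise GridError(f"capacity {name} must be finite and >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.Cs.shape


@dataclass
class CMFConfig:
    """Solver knobs.

    c : augmentation penalty (> 0); also the multiplier step.
    tol : stop when the mean absolute flow residual |div p - ps + pt|
        per voxel falls below tol * mean capacity scale.
    threshold : label cut level t in (0, 1).
    inner_steps : Chambolle projected-gradient steps per outer iteration.
    """

    c: float = 0.3
    max_iter: int = 300
    tol: float = 1e-4
    threshold: float = 0.5
    inner_steps: int = 3

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("augmentation penalty c must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class FlowState:
    """Flows, multiplier and convergence diagnostics of one solve."""

    p: VectorField
    ps: np.ndarray
    pt: np.ndarray
    lam: LabelField
    iterations: int = 0
    residuals: list = field(default_factory=list)
    energies: list = field(default_factory=list)
    converged: bool = False


def primal_energy(lam: LabelField, cap: CapacityField) -> float:
    """Discrete relaxed min-cut energy (sum times voxel volume)."""
    if lam.lam.shape != cap.shape:
        raise GridError("label/capacity grid mismatch")
    g = gradient(lam)
    tv = cap.C * g.norm()
    vol = float(np.prod(cap.spacing))
    return float(
        np.sum((1.0 - lam.lam) * cap.Cs + lam.lam * cap.Ct + tv) * vol
    )


def chambolle_project(p: VectorField, C) -> VectorField:
    """Project each voxel's flow vector onto the ball of radius C(x)."""
    C = np.asarray(C, dtype=np.float64)
    if C.ndim == 0:
        C = np.full(p.shape, float(C))
    if np.any(C < 0):
        raise ValueError("spatial capacity C must be >= 0")
    n = p.norm()
    scale = np.ones_like(n)
    over = n > C
    scale[over] = C[over] / n[over]
    return VectorField(p.px * scale, p.py * scale, p.pz * scale, p.spacing)


def threshold_label(lam: LabelField, t: float = 0.5) -> BinaryMask:
    """Binary mask: 1 where lam(x) > t."""
    if not 0 < t < 1:
        raise ValueError(f"threshold t must lie in (0, 1), got {t}")
    return BinaryMask((lam.lam > t).astype(np.uint8), lam.spacing)


def solve_cmf(cap: CapacityField, cfg: CMFConfig | None = None) -> FlowState:
    """Run the augmented-Lagrangian continuous max-flow to convergence.

    Returns the best iterate with ``converged=False`` (never raises) if
    ``max_iter`` is exhausted before the residual tolerance is met.
    """
    cfg = cfg or CMFConfig()
    shape = cap.shape
    sp = cap.spacing
    c = cfg.c

    p = VectorField.zeros(shape, sp)
    ps = np.minimum(cap.Cs, cap.Ct).copy()
    pt = ps.copy()
    lam = np.full(shape, 0.5)

    # contraction-safe Chambolle step for the 3-D Laplacian, ||div grad|| <= 12/h^2
    h2 = min(sp) ** 2
    tau = h2 / (12.0 * c)

    scale = max(float(np.mean(cap.Cs + cap.Ct)), 1e-12)
    residuals: list = []
    energies: list = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # --- spatial flow: minimize ||div p - F||^2 s.t. |p| <= C
        F = ps - pt + lam / c
        for _ in range(cfg.inner_steps):
            r = divergence(p) - F
            gr = _grad_raw(r, sp)
            p = chambolle_project(
                VectorField(
                    p.px + tau * c * gr[0],
                    p.py + tau * c * gr[1],
                    p.pz + tau * c * gr[2],
                    sp,
                ),
                cap.C,
            )
        div_p = divergence(p)
        # --- source flow: ps = div p + pt + (1 - lam)/c, capped at Cs
        ps = np.minimum(div_p + pt + (1.0 - lam) / c, cap.Cs)
        # --- sink flow: pt = ps - div p + lam/c, capped at Ct
        pt = np.minimum(ps - div_p + lam / c, cap.Ct)
        # --- multiplier
        resid = div_p - ps + pt
        lam = np.clip(lam - c * resid, 0.0, 1.0)

        res = float(np.mean(np.abs(resid)))
        residuals.append(res)
        energies.append(primal_energy(LabelField(lam, sp), cap))
        if res < cfg.tol * scale:
            converged = True
            break

    return FlowState(
        p=p,
        ps=ps,
        pt=pt,
        lam=LabelField(lam, sp),
        iterations=it,
        residuals=residuals,
        energies=energies,
        converged=converged,
    )


def _grad_raw(a: np.ndarray, spacing) -> tuple:
    """Forward-difference gradient of an unconstrained scalar field."""
    from .core_grid_io import _forward_diff

    hx, hy, hz = spacing
    return (
        _forward_diff(a, 0, hx),
        _forward_diff(a, 1, hy),
        _forward_diff(a, 2, hz),
    )
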
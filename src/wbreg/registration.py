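"""Two-stage multiresolution registration driver.

Stage 1 recovers a 6-parameter rigid pre-alignment, stage 2 a cubic
B-spline free-form deformation, both by stochastic steepest ascent on
normalized mutual information: every iteration draws a fresh random set
of sample points, evaluates the analytic NMI gradient, and takes a step
whose length follows the decaying gain rule

    step(k) = a / (A + k + 1)^alpha

with per-resolution-level parameters.  The default configuration is the
clinical whole-body protocol (five rigid levels from 16x-downsampled to
full resolution, five elastic levels, ~8000 iterations per stage, 32
histogram bins, 5000/4096 samples, 8-voxel control-point spacing);
:meth:`RegistrationConfig.compact` is a scaled-down schedule suited to
small (~64^3) volumes such as the synthetic phantoms.

The gradient is normalized before stepping (unit Euclidean norm for the
six rigid parameters, unit max-norm over control points for the FFD), so
the gain ``a`` is calibrated in millimetres of parameter motion; rotation
parameters are scaled by the fixed-image half-diagonal so one step unit
moves corner voxels comparably to a translation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import GeometryError, Volume
from .similarity import DegenerateSampleError, NMISampler
from .transforms import BSplineGrid, RigidTransform, TransformChain

__all__ = [
    "ScheduleEntry",
    "RegistrationConfig",
    "RegistrationError",
    "step_size",
    "build_pyramid",
    "register_rigid",
    "register_bspline",
    "resample",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScheduleEntry:
    """One multiresolution level: downsampling factor, iteration budget, gain rule."""

    factor: int
    iterations: int
    a: float
    A: float = 50.0
    alpha: float = 0.6

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("resolution factor must be >= 1")
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.a <= 0 or self.A < 0 or not (0 < self.alpha <= 1):
            raise ValueError(
                f"invalid gain parameters a={self.a}, A={self.A}, alpha={self.alpha}"
            )


def step_size(k: int, a: float, A: float, alpha: float) -> float:
    """Decaying gain a / (A + k + 1)^alpha, strictly decreasing in k."""
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    ScheduleEntry(1, 1, a, A, alpha)  # parameter validation
    return a / (A + k + 1) ** alpha


@dataclass
class RegistrationConfig:
    """All tunables of the two-stage pipeline.

    The zero-argument constructor reproduces the clinical whole-body
    protocol: rigid levels 16/8/4/2/1 with 4096/2048/1024/512/256
    iterations and gain a=4000, A=50, alpha=0.6; elastic levels 8/4/4/2/2
    with the same iteration ladder and per-level gains
    2000/7000/20000/20000/30000, alpha=0.602.
    """

    rigid_schedule: tuple = field(
        default_factory=lambda: tuple(
            ScheduleEntry(f, it, 4000.0, 50.0, 0.6)
            for f, it in zip((16, 8, 4, 2, 1), (4096, 2048, 1024, 512, 256))
        )
    )
    elastic_schedule: tuple = field(
        default_factory=lambda: tuple(
            ScheduleEntry(f, it, a, 50.0, 0.602)
            for f, it, a in zip(
                (8, 4, 4, 2, 2),
                (4096, 2048, 1024, 512, 256),
                (2000.0, 7000.0, 20000.0, 20000.0, 30000.0),
            )
        )
    )
    bins: int = 32
    rigid_samples: int = 5000
    elastic_samples: int = 4096
    grid_spacing_voxels: int = 8
    control_points_per_iteration: int = 5000
    interim_order: int = 1
    final_order: int = 3
    seed: int = 0
    default_intensity: float | None = None  # out-of-volume fill; None = moving minimum

    @classmethod
    def compact(cls, seed: int = 0) -> "RegistrationConfig":
        """Scaled-down schedule for ~64^3 volumes (phantom experiments).

        Gains are calibrated so the first step at each level is roughly
        one (coarse) voxel and decays below half a millimetre; 51^0.6 is
        the k=0 denominator, so a = step0 * 51^0.6 ~ 10.6 * step0.  The
        elastic stage runs a single full-resolution level: a 64^3 volume
        is already at the scale of a clinical coarse level, and coarser
        elastic levels over-smooth small structures (the head) and bias
        the recovered field.
        """
        return cls(
            rigid_schedule=(
                ScheduleEntry(4, 300, 21.0, 50.0, 0.6),
                ScheduleEntry(2, 150, 10.5, 50.0, 0.6),
                ScheduleEntry(1, 80, 5.3, 50.0, 0.6),
            ),
            elastic_schedule=(ScheduleEntry(1, 400, 2.5, 50.0, 0.602),),
            rigid_samples=5000,
            elastic_samples=4096,
            seed=seed,
        )


def build_pyramid(vol: Volume, factor: int) -> Volume:
    """Gaussian-smoothed, subsampled copy; factor 1 returns the original image.

    Smoothing sigma is factor/2 voxels per axis (a standard anti-alias
    choice); the voxel spacing is multiplied by the factor.
    """
    if factor < 1:
        raise GeometryError("pyramid factor must be >= 1")
    if factor == 1:
        return Volume(vol.data.copy(), vol.spacing.copy(), vol.origin.copy())
    if factor >= min(vol.shape):
        raise GeometryError(
            f"pyramid factor {factor} too large for volume of shape {vol.shape}"
        )
    smoothed = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=float), sigma=factor / 2.0, mode="nearest"
    )
    sub = smoothed[::factor, ::factor, ::factor]
    return Volume(sub, vol.spacing * factor, vol.origin.copy())


def _sample_points(rng: np.random.Generator, vol: Volume, n: int) -> np.ndarray:
    lo, hi = vol.bounds
    return rng.uniform(lo, hi, size=(n, 3))


def _center_of_mass(vol: Volume) -> np.ndarray:
    w = np.asarray(vol.data, dtype=float)
    w = w - w.min()
    total = w.sum()
    if total == 0:
        return vol.center
    idx = np.array(ndimage.center_of_mass(w))
    return vol.origin + idx * vol.spacing


def register_rigid(fixed: Volume, moving: Volume, config: RegistrationConfig):
    """Recover the 6-parameter rigid transform by multiresolution ascent on NMI.

    Returns ``(RigidTransform, trace)`` where the trace is a DataFrame of
    the metric value and step length at every iteration.
    """
    rng = np.random.default_rng(config.seed)
    # centre-of-mass initialization: moving = rigid(fixed) needs t such that
    # fixed mass centre maps onto the moving one
    translation = _center_of_mass(moving) - _center_of_mass(fixed)
    center = fixed.center
    theta = np.concatenate([np.zeros(3), translation])  # (rx, ry, rz, tx, ty, tz)
    lo, hi = fixed.bounds
    half_diag = 0.5 * float(np.linalg.norm(hi - lo))
    scale = np.array([half_diag] * 3 + [1.0] * 3)

    rows = []
    for level, entry in enumerate(config.rigid_schedule):
        fpyr = build_pyramid(fixed, entry.factor)
        mpyr = build_pyramid(moving, entry.factor)
        sampler = NMISampler(fpyr, mpyr, config.bins)
        for k in range(entry.iterations):
            pts = _sample_points(rng, fpyr, config.rigid_samples)
            rigid = RigidTransform(theta[:3], theta[3:], center)
            try:
                value, grad = sampler.value_and_gradient(
                    TransformChain(rigid), pts, wrt="rigid"
                )
            except DegenerateSampleError as exc:
                if level == 0 and k == 0:
                    raise RegistrationError(f"degenerate metric at start: {exc}")
                rows.append(("rigid", level, k, np.nan, 0.0))
                continue
            g = grad / scale  # gradient w.r.t. scaled parameters (theta_s = theta * scale)
            norm = np.linalg.norm(g)
            step = step_size(k, entry.a, entry.A, entry.alpha)
            if norm > 1e-30:
                theta = theta + step * (g / norm) / scale
            rows.append(("rigid", level, k, value, step))
    trace = pd.DataFrame(rows, columns=["stage", "level", "iteration", "nmi", "step"])
    return RigidTransform(theta[:3], theta[3:], center), trace


def register_bspline(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform,
    config: RegistrationConfig,
):
    """Refine a rigid pre-alignment with a B-spline FFD (ascent on NMI).

    The control grid has ``config.grid_spacing_voxels`` fixed-image voxels
    of spacing per axis and covers the rigidly-mapped fixed domain with a
    one-control-point margin.  Each iteration draws fresh histogram
    samples and, when the grid is large, updates only a random subset of
    control points.  Returns ``(TransformChain, trace)``.
    """
    if not np.all(np.isfinite(init.rotation)) or not np.all(np.isfinite(init.translation)):
        raise RegistrationError("initial rigid transform is not finite")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid_spacing = config.grid_spacing_voxels * fixed.spacing
    lo, hi = fixed.bounds
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    mapped = init.apply(corners)
    grid = BSplineGrid.covering(mapped.min(axis=0), mapped.max(axis=0), grid_spacing)
    ncp = int(np.prod(grid.shape))

    rows = []
    for level, entry in enumerate(config.elastic_schedule):
        if entry.iterations == 0:
            continue
        fpyr = build_pyramid(fixed, entry.factor)
        mpyr = build_pyramid(moving, entry.factor)
        sampler = NMISampler(fpyr, mpyr, config.bins)
        gain_ref = None  # initial gradient max-norm; calibrates the gain in mm
        for k in range(entry.iterations):
            pts = _sample_points(rng, fpyr, config.elastic_samples)
            chain = TransformChain(init, grid)
            try:
                value, grad = sampler.value_and_gradient(chain, pts, wrt="ffd")
            except DegenerateSampleError as exc:
                if level == 0 and k == 0:
                    raise RegistrationError(f"degenerate metric at start: {exc}")
                rows.append(("elastic", level, k, np.nan, 0.0))
                continue
            gflat = grad.reshape(ncp, 3)
            if config.control_points_per_iteration < ncp:
                subset = rng.choice(ncp, config.control_points_per_iteration, replace=False)
                g = np.zeros_like(gflat)
                g[subset] = gflat[subset]
            else:
                g = gflat
            if gain_ref is None:
                gain_ref = max(np.abs(g).max(), 1e-30)
            # step(k) is the displacement (mm) a control point with the
            # level's initial peak gradient would take; weaker and
            # near-converged gradients move proportionally less, which
            # keeps unconstrained regions from random-walking.
            step = step_size(k, entry.a, entry.A, entry.alpha)
            grid.coefficients += (step / gain_ref) * g.reshape(grid.coefficients.shape)
            rows.append(("elastic", level, k, value, step))
    trace = pd.DataFrame(rows, columns=["stage", "level", "iteration", "nmi", "step"])
    return TransformChain(init, grid), trace


def resample(
    moving: Volume,
    chain: TransformChain,
    reference: Volume,
    order: int = 3,
    default: float | None = None,
) -> Volume:
    """Resample the moving image onto the reference grid through the chain.

    Each output voxel reads the moving image at ``chain(voxel centre)``
    with B-spline interpolation of the given order (0 for labels, 1
    interim, 3 final).  Reads outside the moving volume take ``default``
    (the moving minimum when None).
    """
    if order not in (0, 1, 3):
        raise ValueError("interpolation order must be 0, 1 or 3")
    if default is None:
        default = float(np.min(moving.data))
    pts = reference.voxel_centers()
    y = chain.apply(pts, outside_zero=True)
    vox = moving.physical_to_voxel(y)
    vals = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        vox.T,
        order=order,
        mode="constant",
        cval=float(default),
    )
    out = vals.reshape(reference.shape)
    if np.issubdtype(moving.data.dtype, np.integer) and order == 0:
        out = out.astype(moving.data.dtype)
    return Volume(out, reference.spacing.copy(), reference.origin.copy())
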
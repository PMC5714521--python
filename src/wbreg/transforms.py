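"""Rigid and cubic B-spline free-form deformation transforms.

A :class:`TransformChain` maps physical points of the *fixed* (CT) domain
into the *moving* (MR) domain — the resampling direction: the moving image
is interpolated at the mapped position of each fixed voxel.  The chain is
a 6-parameter rigid transform optionally followed by a free-form
deformation (FFD) whose displacement field is a cubic B-spline on a
uniform control-point grid, evaluated in the rigidly-mapped frame:

    T(p) = r(p) + u(r(p)),      r(p) = R (p - c) + c + t

with R the composed Euler rotation (X, then Y, then Z), c the rotation
centre and t the translation.  All quantities are in mm.

Transform chains round-trip through a human-readable ASCII key-value
parameter file (elastix-inspired), the exchange format of the pipeline.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._bspline import cubic_dweights, cubic_weights


class TransformFormatError(ValueError):
    """Malformed transform-parameter file."""


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _drot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]], dtype=float)


def _drot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]], dtype=float)


def _drot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0], [c, -s, 0], [0, 0, 0]], dtype=float)


@dataclass
class RigidTransform:
    """Six-parameter rigid transform: three Euler angles (rad) + translation (mm).

    The rotation is applied about ``center`` (mm), X axis first, then Y,
    then Z: R = Rz @ Ry @ Rx.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        return _rot_z(rz) @ _rot_y(ry) @ _rot_x(rx)

    def matrix_derivatives(self) -> list:
        """dR/d(angle) for the three Euler angles, in parameter order."""
        rx, ry, rz = self.rotation
        Rx, Ry, Rz = _rot_x(rx), _rot_y(ry), _rot_z(rz)
        return [
            Rz @ Ry @ _drot_x(rx),
            Rz @ _drot_y(ry) @ Rx,
            _drot_z(rz) @ Ry @ Rx,
        ]

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - self.center) @ self.matrix.T + self.center + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "_MatrixRigid":
        """Exact inverse as matrix + offset (not a Euler re-parameterization)."""
        return _MatrixRigid(self.matrix.T, self.center + self.translation, self.center)


class _MatrixRigid:
    """Internal rigid inverse: q -> R^T (q - shift) + back."""

    def __init__(self, mat, shift, back):
        self.matrix = mat
        self.shift = np.asarray(shift, dtype=float)
        self.back = np.asarray(back, dtype=float)

    def apply(self, points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - self.shift) @ self.matrix.T + self.back
        return out[0] if np.asarray(points).ndim == 1 else out


def rigid_apply(t: RigidTransform, p) -> np.ndarray:
    return t.apply(p)


def bspline_weights(u: float) -> np.ndarray:
    """Four cubic B-spline basis values at fractional offset u in [0, 1)."""
    return cubic_weights(np.asarray(u, dtype=float))


@dataclass
class BSplineGrid:
    """Cubic B-spline displacement field on a uniform control-point grid.

    ``coefficients`` has shape (nx, ny, nz, 3): one displacement vector
    (mm) per control point.  The physical position of control point
    (i, j, k) is ``origin + (i, j, k) * spacing``.  A point p is inside
    the grid's support when its continuous grid coordinate lies in
    [1, n - 2) on every axis (full 4-tap cubic support available); the
    grid must therefore extend one control point beyond the domain it
    deforms on each side.
    """

    coefficients: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValueError("control grid needs at least 4 points per axis (cubic support)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.coefficients.shape[:3]

    @classmethod
    def covering(cls, lo, hi, spacing) -> "BSplineGrid":
        """Zero grid whose support covers the physical box [lo, hi]."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        spacing = np.asarray(spacing, dtype=float).reshape(3)
        shape = np.ceil((hi - lo) / spacing).astype(int) + 4
        origin = lo - spacing
        return cls(np.zeros(tuple(shape) + (3,)), spacing, origin)

    def grid_coords(self, points) -> np.ndarray:
        return (np.atleast_2d(np.asarray(points, dtype=float)) - self.origin) / self.spacing

    def supports(self, points) -> np.ndarray:
        g = self.grid_coords(points)
        n = np.array(self.shape)
        return np.all((g >= 1.0) & (g < n - 2), axis=1)

    def displacement(self, points, check: bool = True, outside_zero: bool = False):
        """FFD displacement (mm) at physical points.

        ``check`` raises on points outside the support; ``outside_zero``
        instead returns a zero displacement there (used by synthesis code
        that must evaluate the field on an open domain).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.grid_coords(pts)
        ok = self.supports(pts)
        if not np.all(ok):
            if check and not outside_zero:
                bad = pts[~ok][0]
                raise ValueError(f"point {bad} outside B-spline grid support")
            g = g.copy()
            g[~ok] = 1.0  # evaluated then zeroed
        disp = _tensor_displacement(self.coefficients, g)
        if not np.all(ok):
            disp[~ok] = 0.0
        return disp[0] if np.asarray(points).ndim == 1 else disp

    def displacement_jacobian(self, points) -> np.ndarray:
        """(N, 3, 3) du_i/dx_j (dimensionless) at physical points inside support."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.grid_coords(pts)
        if not np.all(self.supports(pts)):
            raise ValueError("point outside B-spline grid support")
        jac = _tensor_jacobian(self.coefficients, g)  # d disp / d grid-coord
        return jac / self.spacing[None, None, :]

    def support_indices(self, points):
        """Per-point (base, weights) of the 4x4x4 support; used by the metric gradient."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self.grid_coords(pts)
        base = np.floor(g).astype(np.int64) - 1
        u = g - np.floor(g)
        w = (
            cubic_weights(u[:, 0])[:, :, None, None]
            * cubic_weights(u[:, 1])[:, None, :, None]
            * cubic_weights(u[:, 2])[:, None, None, :]
        )
        return base, w


def _tensor_displacement(coeffs, g):
    base = np.floor(g).astype(np.int64) - 1
    u = g - np.floor(g)
    wx = cubic_weights(u[:, 0])
    wy = cubic_weights(u[:, 1])
    wz = cubic_weights(u[:, 2])
    out = np.zeros((g.shape[0], 3))
    for a in range(4):
        for b in range(4):
            wxy = wx[:, a] * wy[:, b]
            for c in range(4):
                cval = coeffs[base[:, 0] + a, base[:, 1] + b, base[:, 2] + c]
                out += (wxy * wz[:, c])[:, None] * cval
    return out


def _tensor_jacobian(coeffs, g):
    base = np.floor(g).astype(np.int64) - 1
    u = g - np.floor(g)
    w = [cubic_weights(u[:, i]) for i in range(3)]
    d = [cubic_dweights(u[:, i]) for i in range(3)]
    out = np.zeros((g.shape[0], 3, 3))
    for a in range(4):
        for b in range(4):
            for c in range(4):
                cval = coeffs[base[:, 0] + a, base[:, 1] + b, base[:, 2] + c]
                out[:, :, 0] += (d[0][:, a] * w[1][:, b] * w[2][:, c])[:, None] * cval
                out[:, :, 1] += (w[0][:, a] * d[1][:, b] * w[2][:, c])[:, None] * cval
                out[:, :, 2] += (w[0][:, a] * w[1][:, b] * d[2][:, c])[:, None] * cval
    return out


def ffd_displacement(grid: BSplineGrid, p) -> np.ndarray:
    return grid.displacement(p)


@dataclass
class TransformChain:
    """Rigid pre-alignment plus optional FFD refinement (fixed -> moving, mm)."""

    rigid: RigidTransform = field(default_factory=RigidTransform)
    ffd: BSplineGrid | None = None

    def apply(self, points, outside_zero: bool = False) -> np.ndarray:
        y = self.rigid.apply(points)
        if self.ffd is not None:
            y = y + self.ffd.displacement(y, outside_zero=outside_zero)
        return y


def chain_apply(chain: TransformChain, p) -> np.ndarray:
    return chain.apply(p)


# ---------------------------------------------------------------------------
# ASCII transform-parameter file
#
# Key-value text file; Coefficients are flattened x-fastest (x, then y,
# then z, displacement component slowest) and wrapped over multiple lines.


def write_transform_file(chain: TransformChain, path) -> None:
    with open(os.fspath(path), "w") as fh:
        kind = "rigid" if chain.ffd is None else "rigid+bspline"
        fh.write(f"Transform: {kind}\n")
        r = chain.rigid
        params = np.concatenate([r.rotation, r.translation])
        fh.write("RigidParameters: " + " ".join("%.17g" % v for v in params) + "\n")
        fh.write("RigidCenter: " + " ".join("%.17g" % v for v in r.center) + "\n")
        if chain.ffd is not None:
            g = chain.ffd
            fh.write("GridShape: " + " ".join(str(n) for n in g.shape) + "\n")
            fh.write("GridSpacing: " + " ".join("%.17g" % v for v in g.spacing) + "\n")
            fh.write("GridOrigin: " + " ".join("%.17g" % v for v in g.origin) + "\n")
            flat = np.ravel(g.coefficients, order="F")  # x fastest, component slowest
            fh.write("Coefficients:\n")
            for i in range(0, flat.size, 6):
                fh.write(" ".join("%.17g" % v for v in flat[i : i + 6]) + "\n")


def read_transform_file(path) -> TransformChain:
    path = os.fspath(path)
    entries: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ":" in ln and ln.split(":", 1)[0].replace(" ", "").isalpha():
                key, _, rest = ln.partition(":")
                current = key.strip()
                entries[current] = rest.split()
            elif current is not None:
                entries[current].extend(ln.split())
            else:
                raise TransformFormatError(f"{path}: stray data before any key: {ln!r}")

    def need(key, n=None):
        if key not in entries:
            raise TransformFormatError(f"{path}: missing key {key!r}")
        vals = entries[key]
        if n is not None and len(vals) != n:
            raise TransformFormatError(
                f"{path}: key {key!r} expects {n} values, got {len(vals)}"
            )
        return vals

    kind = " ".join(need("Transform"))
    if kind not in ("rigid", "rigid+bspline"):
        raise TransformFormatError(f"{path}: unknown Transform kind {kind!r}")
    try:
        params = np.array([float(v) for v in need("RigidParameters", 6)])
        center = np.array([float(v) for v in need("RigidCenter", 3)])
    except ValueError as exc:
        raise TransformFormatError(f"{path}: non-numeric rigid parameter ({exc})")
    rigid = RigidTransform(params[:3], params[3:], center)
    if kind == "rigid":
        return TransformChain(rigid, None)
    try:
        shape = tuple(int(v) for v in need("GridShape", 3))
        spacing = np.array([float(v) for v in need("GridSpacing", 3)])
        origin = np.array([float(v) for v in need("GridOrigin", 3)])
    except ValueError as exc:
        raise TransformFormatError(f"{path}: malformed grid geometry ({exc})")
    count = int(np.prod(shape)) * 3
    vals = need("Coefficients")
    if len(vals) != count:
        raise TransformFormatError(
            f"{path}: key 'Coefficients' expects {count} values for grid shape "
            f"{shape}, got {len(vals)}"
        )
    try:
        flat = np.array([float(v) for v in vals])
    except ValueError as exc:
        raise TransformFormatError(f"{path}: non-numeric coefficient ({exc})")
    coeffs = flat.reshape(tuple(shape) + (3,), order="F")
    return TransformChain(rigid, BSplineGrid(coeffs, spacing, origin))
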
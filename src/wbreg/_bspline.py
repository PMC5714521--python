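"""Cubic B-spline kernel and tensor-product interpolation.

The uniform cubic B-spline is the single primitive behind three distinct
roles in this package: the free-form deformation field, the smooth
interpolant of the moving image (and its spatial gradient), and the Parzen
window of the differentiable joint histogram.  Everything here works on
arrays of evaluation points at once.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "cubic_weights",
    "cubic_dweights",
    "cubic_d2weights",
    "kernel",
    "kernel_derivative",
    "tensor_interpolate",
]


def cubic_weights(u: np.ndarray) -> np.ndarray:
    """Four cubic B-spline basis values for fractional offsets ``u`` in [0, 1).

    Returns an array of shape ``u.shape + (4,)`` holding the weights of the
    four control points at grid offsets (-1, 0, 1, 2) relative to the
    interval containing the evaluation point.  Rows sum to 1 (partition of
    unity).  At u = 0 the weights are (1/6, 4/6, 1/6, 0).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u >= 1.0):
        raise ValueError("cubic B-spline offset u must satisfy 0 <= u < 1")
    u2 = u * u
    u3 = u2 * u
    w = np.empty(u.shape + (4,), dtype=float)
    w[..., 0] = (1.0 - 3.0 * u + 3.0 * u2 - u3) / 6.0   # (1-u)^3 / 6
    w[..., 1] = (4.0 - 6.0 * u2 + 3.0 * u3) / 6.0
    w[..., 2] = (1.0 + 3.0 * u + 3.0 * u2 - 3.0 * u3) / 6.0
    w[..., 3] = u3 / 6.0
    return w


def cubic_dweights(u: np.ndarray) -> np.ndarray:
    """Derivatives of :func:`cubic_weights` with respect to ``u``.

    Same shape convention; rows sum to 0.
    """
    u = np.asarray(u, dtype=float)
    u2 = u * u
    d = np.empty(u.shape + (4,), dtype=float)
    d[..., 0] = -(1.0 - u) ** 2 / 2.0
    d[..., 1] = (3.0 * u2 - 4.0 * u) / 2.0
    d[..., 2] = (-3.0 * u2 + 2.0 * u + 1.0) / 2.0
    d[..., 3] = u2 / 2.0
    return d


def cubic_d2weights(u: np.ndarray) -> np.ndarray:
    """Second derivatives of :func:`cubic_weights` with respect to ``u``."""
    u = np.asarray(u, dtype=float)
    d2 = np.empty(u.shape + (4,), dtype=float)
    d2[..., 0] = 1.0 - u
    d2[..., 1] = 3.0 * u - 2.0
    d2[..., 2] = 1.0 - 3.0 * u
    d2[..., 3] = u
    return d2


def kernel(t: np.ndarray) -> np.ndarray:
    """Centered cubic B-spline kernel beta3(t), support |t| < 2."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    inner = t < 1.0
    outer = (t >= 1.0) & (t < 2.0)
    ti = t[inner]
    out[inner] = (4.0 - 6.0 * ti * ti + 3.0 * ti ** 3) / 6.0
    to = t[outer]
    out[outer] = (2.0 - to) ** 3 / 6.0
    return out


def kernel_derivative(t: np.ndarray) -> np.ndarray:
    """d beta3 / dt (odd function, support |t| < 2)."""
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    out = np.zeros_like(a)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    ai = a[inner]
    out[inner] = (-12.0 * ai + 9.0 * ai * ai) / 6.0
    ao = a[outer]
    out[outer] = -3.0 * (2.0 - ao) ** 2 / 6.0
    return out * np.sign(t)


def _mirror_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Reflect out-of-range indices with the 'mirror' rule (period 2n-2).

    Matches scipy.ndimage.spline_filter(mode='mirror'): d c b | a b c d | c b a.
    """
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def tensor_interpolate(
    coeffs: np.ndarray,
    g: np.ndarray,
    gradient: bool = False,
    mirror: bool = True,
):
    """Evaluate a 3D cubic-spline tensor product at continuous grid coords.

    Parameters
    ----------
    coeffs
        Spline coefficient array of shape (nx, ny, nz) or (nx, ny, nz, C)
        for C-channel fields (e.g. a displacement field with C=3).  For
        image interpolation these must be prefiltered coefficients
        (scipy.ndimage.spline_filter, mode='mirror'); for a B-spline FFD
        they are the control-point values themselves.
    g
        (N, 3) continuous grid coordinates (units of grid cells).
    gradient
        If True also return the derivative along each axis, in units of
        value per grid cell.
    mirror
        Reflect the 4-tap support at the array edges.  When False the
        caller guarantees that the full support lies inside the array.

    Returns
    -------
    values : (N,) or (N, C)
    grads  : (N, 3) or (N, 3, C), only when ``gradient`` is True.
    """
    g = np.asarray(g, dtype=float)
    base = np.floor(g).astype(np.int64)
    u = g - base
    # guard the exact upper edge: floor(g)==g at integers keeps u==0, fine
    base -= 1  # support taps base .. base+3

    wx = cubic_weights(u[:, 0])
    wy = cubic_weights(u[:, 1])
    wz = cubic_weights(u[:, 2])
    if gradient:
        dwx = cubic_dweights(u[:, 0])
        dwy = cubic_dweights(u[:, 1])
        dwz = cubic_dweights(u[:, 2])

    nx, ny, nz = coeffs.shape[:3]
    channels = coeffs.shape[3:] if coeffs.ndim == 4 else ()

    ix = base[:, 0, None] + np.arange(4)
    iy = base[:, 1, None] + np.arange(4)
    iz = base[:, 2, None] + np.arange(4)
    if mirror:
        ix = _mirror_index(ix, nx)
        iy = _mirror_index(iy, ny)
        iz = _mirror_index(iz, nz)

    n = g.shape[0]
    val = np.zeros((n,) + channels, dtype=float)
    if gradient:
        grad = np.zeros((n, 3) + channels, dtype=float)

    for a in range(4):
        for b in range(4):
            wxy = wx[:, a] * wy[:, b]
            if gradient:
                dxy = dwx[:, a] * wy[:, b]
                xdy = wx[:, a] * dwy[:, b]
            for c in range(4):
                cval = coeffs[ix[:, a], iy[:, b], iz[:, c]]
                if channels:
                    w = (wxy * wz[:, c])[:, None]
                    val += w * cval
                    if gradient:
                        grad[:, 0] += (dxy * wz[:, c])[:, None] * cval
                        grad[:, 1] += (xdy * wz[:, c])[:, None] * cval
                        grad[:, 2] += (wxy * dwz[:, c])[:, None] * cval
                else:
                    val += wxy * wz[:, c] * cval
                    if gradient:
                        grad[:, 0] += dxy * wz[:, c] * cval
                        grad[:, 1] += xdy * wz[:, c] * cval
                        grad[:, 2] += wxy * dwz[:, c] * cval
    if gradient:
        return val, grad
    return val
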
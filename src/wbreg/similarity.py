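"""Joint histograms and normalized mutual information from spatial samples.

NMI = (H_fixed + H_moving) / H_joint is the similarity measure driving the
registration: it rewards a *predictable* relationship between the two
intensity distributions rather than any particular (e.g. linear) mapping,
which is what makes it usable across modalities whose tissue contrasts
disagree.

Two histogram windows are supported:

* ``"nearest"`` — plain binning on both axes.  Exact in its limits
  (identical discretized images give NMI = 2, independent images 1) and
  exactly invariant under relabeling of intensity classes; used for
  analysis and reporting.
* ``"parzen"`` — cubic B-spline window on the moving axis, linear on the
  fixed axis (the standard differentiable construction).  The histogram
  then depends smoothly on the transform parameters, giving an analytic
  NMI gradient through the moving-image interpolant; used by the
  optimizer.

Entropies are in nats; NMI is base-invariant as a ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._bspline import cubic_dweights, cubic_weights, tensor_interpolate
from .core import Volume
from .transforms import TransformChain

__all__ = [
    "JointHistogram",
    "NMISampler",
    "DegenerateSampleError",
    "build_joint_histogram",
    "nmi",
    "nmi_gradient",
]

_EDGE = 1.0 - 1e-12  # keeps the top intensity strictly inside the last bin


class DegenerateSampleError(RuntimeError):
    """Too few usable samples (or too many mapped outside the moving volume)."""


@dataclass
class JointHistogram:
    """Fractional joint counts plus the binning metadata that produced them."""

    counts: np.ndarray
    fixed_range: tuple
    moving_range: tuple
    n_samples: int
    n_skipped: int = 0

    @property
    def bins(self) -> int:
        return self.counts.shape[0]


def robust_range(data: np.ndarray, lo_pct: float = 0.5, hi_pct: float = 99.5) -> tuple:
    """Robust intensity range (percentiles) used to fix the binning per level."""
    lo, hi = np.percentile(data, [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def nmi(hist: JointHistogram | np.ndarray) -> float:
    """Normalized mutual information (H_f + H_m) / H_joint of a histogram.

    Zero-mass bins contribute zero.  A histogram with a single occupied
    cell has zero joint entropy; the defined degenerate value 2.0 (the
    identical-image limit) is returned.
    """
    counts = hist.counts if isinstance(hist, JointHistogram) else np.asarray(hist, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateSampleError("histogram has no mass")
    p = counts / total
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    def _entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hj = _entropy(p.reshape(-1))
    if hj == 0.0:
        return 2.0
    return (_entropy(pf) + _entropy(pm)) / hj


class NMISampler:
    """Caches interpolation state for repeated NMI evaluations on one image pair.

    The moving image is interpolated with a cubic B-spline (prefiltered
    coefficients, mirror boundary) so the metric is twice differentiable
    in the transform parameters; the fixed intensity is read with linear
    interpolation at the (fixed, untransformed) sample point.  Samples
    mapping outside the moving volume are skipped; the metric is declared
    invalid when more than ``max_drop_fraction`` of them are lost.
    """

    def __init__(
        self,
        fixed: Volume,
        moving: Volume,
        bins: int = 32,
        fixed_range: tuple | None = None,
        moving_range: tuple | None = None,
        max_drop_fraction: float = 0.8,
    ):
        if bins < 2:
            raise ValueError("need at least 2 histogram bins")
        self.fixed = fixed
        self.moving = moving
        self.bins = int(bins)
        self.fixed_range = fixed_range or robust_range(fixed.data)
        self.moving_range = moving_range or robust_range(moving.data)
        self.max_drop_fraction = max_drop_fraction
        self._fixed_data = np.asarray(fixed.data, dtype=float)
        self._mcoeffs = ndimage.spline_filter(
            np.asarray(moving.data, dtype=float), order=3, mode="mirror"
        )

    # -- sampling ---------------------------------------------------------

    def _fixed_values(self, points: np.ndarray) -> np.ndarray:
        vox = self.fixed.physical_to_voxel(points)
        return ndimage.map_coordinates(self._fixed_data, vox.T, order=1, mode="nearest")

    def _map_points(self, chain: TransformChain, points: np.ndarray):
        """Transform sample points; returns (y, valid mask) in moving physical space."""
        y = chain.apply(points)
        gm = self.moving.physical_to_voxel(y)
        n = np.array(self.moving.shape)
        valid = np.all((gm >= 0.0) & (gm <= n - 1), axis=1)
        return y, gm, valid

    def _moving_values(self, gm: np.ndarray, gradient: bool = False):
        if gradient:
            val, grad = tensor_interpolate(self._mcoeffs, gm, gradient=True)
            return val, grad / self.moving.spacing[None, :]  # per mm
        return tensor_interpolate(self._mcoeffs, gm)

    def _bin_coords(self, f: np.ndarray, m: np.ndarray):
        B = self.bins
        flo, fhi = self.fixed_range
        mlo, mhi = self.moving_range
        ffrac = np.clip((f - flo) / (fhi - flo), 0.0, 1.0)
        mfrac = (m - mlo) / (mhi - mlo)
        m_clipped = (mfrac < 0.0) | (mfrac > 1.0)
        mfrac = np.clip(mfrac, 0.0, 1.0)
        zf = ffrac * (B - 1) * _EDGE          # linear window: taps floor, floor+1
        zm = 1.0 + mfrac * (B - 3) * _EDGE    # cubic window:  taps floor-1 .. floor+2
        return zf, zm, m_clipped

    # -- histogram --------------------------------------------------------

    def histogram(
        self, chain: TransformChain, points: np.ndarray, window: str = "parzen"
    ) -> JointHistogram:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, gm, valid = self._map_points(chain, points)
        n_skipped = int((~valid).sum())
        if points.shape[0] - n_skipped < 2:
            raise DegenerateSampleError(
                f"only {points.shape[0] - n_skipped} usable samples"
            )
        if n_skipped > self.max_drop_fraction * points.shape[0]:
            raise DegenerateSampleError(
                f"{n_skipped}/{points.shape[0]} samples map outside the moving volume"
            )
        f = self._fixed_values(points[valid])
        m = self._moving_values(gm[valid])
        B = self.bins
        if window == "nearest":
            flo, fhi = self.fixed_range
            mlo, mhi = self.moving_range
            fb = np.clip((f - flo) / (fhi - flo) * B, 0, B - 1e-9).astype(int)
            mb = np.clip((m - mlo) / (mhi - mlo) * B, 0, B - 1e-9).astype(int)
            counts = np.bincount(fb * B + mb, minlength=B * B).astype(float)
        elif window == "parzen":
            zf, zm, _ = self._bin_coords(f, m)
            af = np.floor(zf).astype(np.int64)
            uf = zf - af
            wf = np.stack([1.0 - uf, uf], axis=1)                  # (N, 2)
            bm = np.floor(zm).astype(np.int64) - 1
            wm = cubic_weights(zm - np.floor(zm))                  # (N, 4)
            idx = (af[:, None, None] + np.array([0, 1])[None, :, None]) * B + (
                bm[:, None, None] + np.arange(4)[None, None, :]
            )
            w = wf[:, :, None] * wm[:, None, :]
            counts = np.bincount(idx.reshape(-1), w.reshape(-1), minlength=B * B)
        else:
            raise ValueError(f"unknown histogram window {window!r}")
        return JointHistogram(
            counts.reshape(B, B), self.fixed_range, self.moving_range,
            n_samples=int(valid.sum()), n_skipped=n_skipped,
        )

    def value(self, chain: TransformChain, points, window: str = "parzen") -> float:
        return nmi(self.histogram(chain, points, window=window))

    # -- analytic gradient -------------------------------------------------

    def value_and_gradient(
        self,
        chain: TransformChain,
        points: np.ndarray,
        wrt: str = "rigid",
    ):
        """NMI and its partial derivatives through the Parzen histogram.

        ``wrt='rigid'`` returns a (6,) vector over (rx, ry, rz, tx, ty, tz);
        ``wrt='ffd'`` returns the full control-grid gradient of shape
        ``chain.ffd.shape + (3,)``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        y, gm, valid = self._map_points(chain, points)
        if valid.sum() < 2:
            raise DegenerateSampleError(f"only {int(valid.sum())} usable samples")
        if (~valid).sum() > self.max_drop_fraction * points.shape[0]:
            raise DegenerateSampleError("too many samples outside the moving volume")
        pts = points[valid]
        gmv = gm[valid]
        f = self._fixed_values(pts)
        m, mgrad = self._moving_values(gmv, gradient=True)  # (N,), (N, 3) per mm
        N = pts.shape[0]
        B = self.bins

        zf, zm, m_clipped = self._bin_coords(f, m)
        af = np.floor(zf).astype(np.int64)
        uf = zf - af
        wf = np.stack([1.0 - uf, uf], axis=1)
        bm_base = np.floor(zm).astype(np.int64) - 1
        um = zm - np.floor(zm)
        wm = cubic_weights(um)
        dwm = cubic_dweights(um)  # d weight / d zm

        idx = (af[:, None, None] + np.array([0, 1])[None, :, None]) * B + (
            bm_base[:, None, None] + np.arange(4)[None, None, :]
        )
        w = wf[:, :, None] * wm[:, None, :]
        counts = np.bincount(idx.reshape(-1), w.reshape(-1), minlength=B * B)
        p = (counts / N).reshape(B, B)
        pf = p.sum(axis=1)
        pm = p.sum(axis=0)

        def _entropy(q):
            q = q[q > 0]
            return float(-(q * np.log(q)).sum())

        hj = _entropy(p.reshape(-1))
        hf = _entropy(pf)
        hm = _entropy(pm)
        if hj == 0.0:
            raise DegenerateSampleError("degenerate histogram (zero joint entropy)")
        value = (hf + hm) / hj

        # dNMI/dP(a,b); zero-mass cells only ever multiply zero weights.
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
            logpf = np.where(pf > 0, np.log(np.where(pf > 0, pf, 1.0)), 0.0)
            logpm = np.where(pm > 0, np.log(np.where(pm > 0, pm, 1.0)), 0.0)
        G = np.where(
            p > 0,
            (-(2.0 + logpf[:, None] + logpm[None, :]) + value * (1.0 + logp)) / hj,
            0.0,
        )

        # chain rule down to the moving intensity of each sample
        s_m = (B - 3) * _EDGE / (self.moving_range[1] - self.moving_range[0])
        Gflat = G.reshape(-1)
        dP_dm = wf[:, :, None] * dwm[:, None, :] / N  # d p(cell) / d zm per sample
        wi = (Gflat[idx] * dP_dm).sum(axis=(1, 2)) * s_m
        wi[m_clipped] = 0.0  # clipped intensities sit on a flat piece of the window

        q = wi[:, None] * mgrad  # (N, 3): dNMI/dy per sample, mm^-1

        rigid = chain.rigid
        if wrt == "rigid":
            if chain.ffd is not None:
                yr = rigid.apply(pts)
                J = chain.ffd.displacement_jacobian(yr)  # (N, 3, 3)
                amp = np.eye(3)[None] + J
            else:
                amp = None
            grad = np.zeros(6)
            dRs = rigid.matrix_derivatives()
            pc = pts - rigid.center
            for k in range(3):
                dyr = pc @ dRs[k].T
                dy = dyr if amp is None else np.einsum("nij,nj->ni", amp, dyr)
                grad[k] = (q * dy).sum()
            for j in range(3):
                if amp is None:
                    grad[3 + j] = q[:, j].sum()
                else:
                    grad[3 + j] = (q * amp[:, :, j]).sum()
            return value, grad
        if wrt == "ffd":
            if chain.ffd is None:
                raise ValueError("chain has no FFD to differentiate")
            ffd = chain.ffd
            yr = rigid.apply(pts)
            base, wcp = ffd.support_indices(yr)  # (N, 3), (N, 4, 4, 4)
            nx, ny, nz = ffd.shape
            off = np.arange(4)
            ii = base[:, 0, None, None, None] + off[None, :, None, None]
            jj = base[:, 1, None, None, None] + off[None, None, :, None]
            kk = base[:, 2, None, None, None] + off[None, None, None, :]
            flat = (ii * ny + jj) * nz + kk  # (N, 4, 4, 4)
            grad = np.zeros((nx * ny * nz, 3))
            fr = flat.reshape(-1)
            wr = wcp.reshape(len(pts), -1)
            for comp in range(3):
                grad[:, comp] = np.bincount(
                    fr, (wr * q[:, comp : comp + 1]).reshape(-1), minlength=nx * ny * nz
                )
            return value, grad.reshape(nx, ny, nz, 3)
        raise ValueError(f"unknown parameter subset {wrt!r}")


# ---------------------------------------------------------------------------
# module-level convenience wrappers


def build_joint_histogram(
    fixed: Volume,
    moving: Volume,
    chain: TransformChain,
    points,
    bins: int = 32,
    window: str = "parzen",
    fixed_range: tuple | None = None,
    moving_range: tuple | None = None,
) -> JointHistogram:
    sampler = NMISampler(fixed, moving, bins, fixed_range, moving_range)
    return sampler.histogram(chain, np.asarray(points, dtype=float), window=window)


def nmi_gradient(
    fixed: Volume,
    moving: Volume,
    chain: TransformChain,
    points,
    wrt: str = "rigid",
    bins: int = 32,
    fixed_range: tuple | None = None,
    moving_range: tuple | None = None,
):
    """Analytic NMI gradient for a rigid-parameter or FFD-coefficient subset."""
    sampler = NMISampler(fixed, moving, bins, fixed_range, moving_range)
    return sampler.value_and_gradient(chain, np.asarray(points, dtype=float), wrt=wrt)
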
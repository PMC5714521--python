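"""Seeded paired pseudo-CT / pseudo-MR whole-body phantoms with ground truth.

Each case emulates the data situation of a whole-body MR-to-CT
registration study: a CT-like volume on a fine grid (Hounsfield-unit
classes: air ~ -1000, lung ~ -800, soft tissue ~ 40, bone ~ 700), an
MR-like volume on a coarser anisotropic grid whose intensities are a
*non-monotone* per-tissue remap of the same anatomy (so no affine
CT<->MR intensity relation exists) degraded by a smooth multiplicative
bias field and noise, organ label volumes (body, brain, lungs, kidneys)
on both grids, the 16-site landmark roster on both grids, and the exact
fixed->moving transform (rigid + B-spline FFD) used to synthesize the
MR side.

Anatomy is procedural — trunk + head + neck + arm primitives, spherical
brain, ellipsoidal lungs/kidneys/liver, a vertebra-modulated spine and a
skull shell — scaled to the requested field of view.  A smooth shared
"texture" field gives the interior of the body structure in both
modalities, without which interior deformation would be unobservable to
any intensity-driven metric.  Everything is deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelVolume, LandmarkSet, Volume
from .transforms import BSplineGrid, RigidTransform, TransformChain

__all__ = [
    "PhantomConfigError",
    "Anatomy",
    "PhantomCase",
    "REGION_CODES",
    "LANDMARK_SITES",
    "generate_anatomy",
    "mr_from_ct",
    "warp_case",
    "generate_case",
]


class PhantomConfigError(ValueError):
    pass


REGION_CODES = {"body": 1, "brain": 2, "lungs": 3, "kidneys": 4}

# tissue classes (most specific wins)
_AIR, _SOFT, _LUNG, _BRAIN, _KIDNEY, _BONE, _LIVER, _FAT = range(8)

_CT_VALUE = {_AIR: -1000.0, _SOFT: 40.0, _LUNG: -800.0, _BRAIN: 35.0,
             _KIDNEY: 45.0, _BONE: 700.0, _LIVER: 60.0, _FAT: -100.0}
# deliberately non-monotone w.r.t. the CT ordering (bone bright on CT, dark
# on MR; fat dark on CT, bright on T1-like MR)
_MR_VALUE = {_AIR: 5.0, _SOFT: 100.0, _LUNG: 30.0, _BRAIN: 140.0,
             _KIDNEY: 160.0, _BONE: 20.0, _LIVER: 80.0, _FAT: 190.0}
# heterogeneity amplitude of the shared texture field per tissue (CT: HU;
# viscera span roughly -100..+100 HU around the soft-tissue mean)
_CT_TEXTURE = {_AIR: 0.0, _SOFT: 60.0, _LUNG: 40.0, _BRAIN: 8.0,
               _KIDNEY: 10.0, _BONE: 0.0, _LIVER: 25.0, _FAT: 15.0}
_MR_TEXTURE = {_AIR: 0.0, _SOFT: -35.0, _LUNG: 12.0, _BRAIN: 10.0,
               _KIDNEY: 12.0, _BONE: 0.0, _LIVER: 25.0, _FAT: 15.0}

_REFERENCE_EXTENT = np.array([192.0, 192.0, 256.0])

# the 16-site landmark roster, with positions in the reference frame (mm);
# sites without a direct phantom analogue (vertebrae, celiac trunk) sit at
# defined body-axis positions on/near the spine
LANDMARK_SITES = [
    ("Apex of right lung", (66.0, 90.0, 184.0)),
    ("Apex of left lung", (126.0, 90.0, 184.0)),
    ("Liver dome", (66.0, 98.0, 134.0)),
    ("Anterior right liver border", (50.0, 80.0, 112.0)),
    ("Anterior left liver border", (82.0, 78.0, 112.0)),
    ("Lateral liver border", (36.0, 98.0, 112.0)),
    ("Posterior liver border", (66.0, 120.0, 112.0)),
    ("Inferior liver border", (66.0, 98.0, 90.0)),
    ("Right adrenal", (70.0, 112.0, 115.0)),
    ("Celiac trunk", (96.0, 116.0, 108.0)),
    ("Upper tip of right kidney", (70.0, 112.0, 111.0)),
    ("Upper tip of left kidney", (122.0, 112.0, 111.0)),
    ("Lower tip of right kidney", (70.0, 112.0, 73.0)),
    ("Lower tip of left kidney", (122.0, 112.0, 73.0)),
    ("T10 vertebra", (96.0, 128.0, 122.0)),
    ("L5 vertebra", (96.0, 128.0, 42.0)),
]


@dataclass
class PhantomGeometry:
    """Analytic anatomy, scaled from the reference 192x192x256 mm frame."""

    extent: np.ndarray

    def __post_init__(self):
        self.extent = np.asarray(self.extent, dtype=float).reshape(3)
        self.scale = self.extent / _REFERENCE_EXTENT

    def _s(self, ref):
        return np.asarray(ref, dtype=float) * self.scale

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Tissue class codes at arbitrary physical points (vectorized)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) / self.scale
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        cls = np.full(p.shape[0], _AIR, dtype=np.int8)

        trunk = (((x - 96) / 70) ** 2 + ((y - 96) / 50) ** 2 <= 1) & (z >= 8) & (z <= 190)
        head_d2 = (x - 96) ** 2 + (y - 96) ** 2 + (z - 222) ** 2
        head = head_d2 <= 27.0 ** 2
        neck = ((x - 96) ** 2 + (y - 96) ** 2 <= 14 ** 2) & (z > 185) & (z <= 200)
        arm_r = ((x - 14) ** 2 + (y - 96) ** 2 <= 9 ** 2) & (z >= 40) & (z <= 185)
        arm_l = ((x - 178) ** 2 + (y - 96) ** 2 <= 9 ** 2) & (z >= 40) & (z <= 185)
        cls[trunk | head | neck | arm_r | arm_l] = _SOFT

        # subcutaneous fat: outer shell of the trunk cross-section
        inner = (((x - 96) / 62) ** 2 + ((y - 96) / 42) ** 2 <= 1)
        cls[trunk & ~inner] = _FAT

        liver = (((x - 66) / 30) ** 2 + ((y - 98) / 24) ** 2 + ((z - 112) / 22) ** 2) <= 1
        cls[liver & (cls != _AIR)] = _LIVER

        spine = ((x - 96) ** 2 + (y - 128) ** 2 <= 9 ** 2) & (z >= 12) & (z <= 190)
        pelvis = (((x - 96) / 42) ** 2 + ((y - 110) / 26) ** 2 + ((z - 28) / 14) ** 2) <= 1
        skull = head & (head_d2 >= 21.0 ** 2)  # ~6 mm calvarium
        cls[(spine | pelvis | skull) & (cls != _AIR)] = _BONE

        lung_r = (((x - 66) / 24) ** 2 + ((y - 90) / 27) ** 2 + ((z - 148) / 36) ** 2) <= 1
        lung_l = (((x - 126) / 24) ** 2 + ((y - 90) / 27) ** 2 + ((z - 148) / 36) ** 2) <= 1
        cls[lung_r | lung_l] = _LUNG

        kid_r = (((x - 70) / 12) ** 2 + ((y - 112) / 12) ** 2 + ((z - 92) / 19) ** 2) <= 1
        kid_l = (((x - 122) / 12) ** 2 + ((y - 112) / 12) ** 2 + ((z - 92) / 19) ** 2) <= 1
        cls[kid_r | kid_l] = _KIDNEY

        brain = head_d2 <= 19.0 ** 2
        cls[brain] = _BRAIN
        return cls

    def region_labels(self, points: np.ndarray) -> np.ndarray:
        """Most-specific region code (body/brain/lungs/kidneys) at points."""
        cls = self.classify(points)
        lab = np.zeros(cls.shape, dtype=np.int16)
        lab[cls != _AIR] = REGION_CODES["body"]
        lab[cls == _BRAIN] = REGION_CODES["brain"]
        lab[cls == _LUNG] = REGION_CODES["lungs"]
        lab[cls == _KIDNEY] = REGION_CODES["kidneys"]
        return lab

    def bone_modulation(self, points: np.ndarray) -> np.ndarray:
        """Vertebra-like periodic density modulation along the body axis."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) / self.scale
        return 1.0 + 0.25 * np.sin(2.0 * np.pi * p[:, 2] / 16.0)

    def landmarks(self) -> LandmarkSet:
        names = [n for n, _ in LANDMARK_SITES]
        pts = np.array([self._s(p) for _, p in LANDMARK_SITES])
        return LandmarkSet(names, pts)


@dataclass
class Anatomy:
    """CT-side rendering of one phantom: image, labels, landmarks, texture."""

    ct: Volume
    labels: LabelVolume
    landmarks: LandmarkSet
    geometry: PhantomGeometry
    texture: Volume  # smooth unit-variance field shared by both modalities
    seed: int


@dataclass
class PhantomCase:
    """A full paired case with the exact synthesis transform as ground truth."""

    ct: Volume
    mr: Volume
    ct_labels: LabelVolume
    mr_labels: LabelVolume
    ct_landmarks: LandmarkSet
    mr_landmarks: LandmarkSet
    truth: TransformChain
    seed: int


def generate_anatomy(
    seed: int,
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 4.0),
    noise_level: float = 8.0,
) -> Anatomy:
    """Procedural body with organs, rendered as a CT-like volume.

    Deterministic per seed.  The texture field (Gaussian-smoothed seeded
    noise, ~6-voxel correlation length, unit variance) modulates tissue
    intensity in both modalities and is returned so the MR renderer can
    reuse it.
    """
    shape = tuple(int(n) for n in shape)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if min(shape) < 32:
        raise PhantomConfigError(f"phantom grid must be >= 32 per axis, got {shape}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    extent = np.array(shape) * spacing
    geom = PhantomGeometry(extent)

    vol0 = Volume(np.zeros(shape, dtype=np.float32), spacing)
    pts = vol0.voxel_centers()
    cls = geom.classify(pts)

    tex = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0, mode="nearest")
    tex /= max(tex.std(), 1e-12)

    ct_base = np.array([_CT_VALUE[c] for c in range(len(_CT_VALUE))])[cls]
    ct_amp = np.array([_CT_TEXTURE[c] for c in range(len(_CT_VALUE))])[cls]
    hu = ct_base + ct_amp * tex.reshape(-1)
    bone = cls == _BONE
    hu[bone] = _CT_VALUE[_BONE] * geom.bone_modulation(pts[bone])
    hu += rng.normal(scale=noise_level, size=hu.shape)

    labels = geom.region_labels(pts).reshape(shape)
    return Anatomy(
        ct=Volume(hu.reshape(shape).astype(np.float32), spacing),
        labels=LabelVolume(labels, dict(REGION_CODES), spacing),
        landmarks=geom.landmarks(),
        geometry=geom,
        texture=Volume(tex.astype(np.float32), spacing),
        seed=int(seed),
    )


def _mr_grid(anatomy: Anatomy, mr_shape, mr_spacing):
    mr_shape = tuple(int(n) for n in mr_shape)
    if mr_spacing is None:
        mr_spacing = anatomy.geometry.extent / np.array(mr_shape)
    return mr_shape, np.asarray(mr_spacing, dtype=float).reshape(3)


def _invert_chain(chain: TransformChain, q: np.ndarray, iters: int = 30) -> np.ndarray:
    """Numeric inverse of T(p) = r(p) + u(r(p)) at points q (synthesis only).

    Fixed-point iteration on the intermediate frame: y = q - u(y), then
    p = r^-1(y).  Converges because the FFD's displacement gradient is
    bounded well below 1 by the injectivity limit on its magnitude.
    """
    y = q.copy()
    if chain.ffd is not None:
        for _ in range(iters):
            y = q - chain.ffd.displacement(y, outside_zero=True)
    return chain.rigid.inverse().apply(y)


def _render_mr(
    anatomy: Anatomy,
    chain: TransformChain,
    mr_shape,
    mr_spacing,
    rng: np.random.Generator,
    bias_amplitude: float,
    noise_level: float,
    texture_amplitude: float,
):
    """MR image + labels on the moving grid such that chain aligns MR to CT."""
    mr_shape, mr_spacing = _mr_grid(anatomy, mr_shape, mr_spacing)
    grid = Volume(np.zeros(mr_shape, dtype=np.float32), mr_spacing)
    q = grid.voxel_centers()
    p = _invert_chain(chain, q)

    geom = anatomy.geometry
    cls = geom.classify(p)
    base = np.array([_MR_VALUE[c] for c in range(len(_CT_VALUE))])[cls]
    amp = np.array([_MR_TEXTURE[c] for c in range(len(_CT_VALUE))])[cls]
    tex = ndimage.map_coordinates(
        np.asarray(anatomy.texture.data, dtype=float),
        anatomy.texture.physical_to_voxel(p).T,
        order=1, mode="nearest",
    )
    signal = base + texture_amplitude * amp * tex
    bone = cls == _BONE
    signal[bone] *= geom.bone_modulation(p[bone])

    if bias_amplitude > 0:
        bias = ndimage.gaussian_filter(rng.normal(size=mr_shape), sigma=8.0, mode="nearest")
        bias /= max(np.abs(bias).max(), 1e-12)
        signal = signal * (1.0 + bias_amplitude * bias.reshape(-1))
    if noise_level > 0:
        signal = signal + rng.normal(scale=noise_level, size=signal.shape)

    mr = Volume(signal.reshape(mr_shape).astype(np.float32), mr_spacing)
    labels = LabelVolume(
        geom.region_labels(p).reshape(mr_shape), dict(REGION_CODES), mr_spacing
    )
    return mr, labels


def mr_from_ct(
    anatomy: Anatomy,
    seed: int,
    bias_amplitude: float = 0.08,
    noise_level: float = 3.0,
    texture_amplitude: float = 1.0,
    mr_shape=(48, 48, 48),
    mr_spacing=None,
) -> Volume:
    """Unwarped MR-like rendering of the anatomy on a coarser grid.

    Per-tissue intensities follow a non-monotone remap of the CT classes;
    a smooth multiplicative bias field and Gaussian noise emulate MR
    degradation.  With bias, noise and texture amplitudes all zero the
    output is piecewise constant with exactly one intensity per class.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    mr, _ = _render_mr(
        anatomy, TransformChain(), mr_shape, mr_spacing, rng,
        bias_amplitude, noise_level, texture_amplitude,
    )
    return mr


def _truth_ffd(
    anatomy: Anatomy,
    rigid: RigidTransform,
    mr_spacing: np.ndarray,
    mr_shape,
    rng: np.random.Generator,
    magnitude: float,
) -> BSplineGrid:
    grid_spacing = 8.0 * anatomy.ct.spacing
    if magnitude > 0.4 * float(grid_spacing.min()):
        raise PhantomConfigError(
            f"FFD magnitude {magnitude} mm exceeds the injectivity bound "
            f"{0.4 * grid_spacing.min():.1f} mm (0.4 x control spacing)"
        )
    lo_f, hi_f = anatomy.ct.bounds
    corners = np.array(
        [[x, y, z] for x in (lo_f[0], hi_f[0]) for y in (lo_f[1], hi_f[1]) for z in (lo_f[2], hi_f[2])]
    )
    mapped = rigid.apply(corners)
    hi_m = np.array(mr_shape) * mr_spacing
    lo = np.minimum(mapped.min(axis=0), 0.0) - magnitude - grid_spacing
    hi = np.maximum(mapped.max(axis=0), hi_m) + magnitude + grid_spacing
    grid = BSplineGrid.covering(lo, hi, grid_spacing)
    if magnitude > 0:
        c = rng.normal(size=grid.coefficients.shape)
        c = ndimage.gaussian_filter(c, sigma=(1.0, 1.0, 1.0, 0.0), mode="constant")
        c[:2], c[-2:] = 0.0, 0.0
        c[:, :2], c[:, -2:] = 0.0, 0.0
        c[:, :, :2], c[:, :, -2:] = 0.0, 0.0
        norms = np.linalg.norm(c, axis=-1)
        c *= magnitude / max(norms.max(), 1e-12)
        grid.coefficients[:] = c
    return grid


def warp_case(
    anatomy: Anatomy,
    seed: int,
    rigid_magnitude: float = 8.0,
    ffd_magnitude: float = 6.0,
    mr_shape=(48, 48, 48),
    mr_spacing=None,
    bias_amplitude: float = 0.08,
    noise_level: float = 3.0,
    texture_amplitude: float = 1.0,
    translation=None,
    rotation=None,
) -> PhantomCase:
    """Draw a random rigid offset + smooth FFD and synthesize the MR side.

    ``rigid_magnitude`` is the translation length in mm (rotation angles
    scale with it at 0.004 rad/mm, ~2 degrees at the 8 mm default);
    ``ffd_magnitude`` bounds the control-point displacement norm and is
    checked against the injectivity limit of 0.4 x control spacing.
    Explicit ``translation`` (mm) / ``rotation`` (rad) override the random
    draw.  The exact chain used for synthesis is stored as ``truth``:
    applying it to the CT-space landmarks reproduces the MR-space
    landmarks exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    mr_shape, mr_spacing_arr = _mr_grid(anatomy, mr_shape, mr_spacing)

    if translation is not None or rotation is not None:
        translation = np.zeros(3) if translation is None else np.asarray(translation, float)
        angles = np.zeros(3) if rotation is None else np.asarray(rotation, float)
    elif rigid_magnitude > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        translation = direction * rigid_magnitude
        angles = rng.uniform(-1.0, 1.0, size=3) * 0.004 * rigid_magnitude
    else:
        translation = np.zeros(3)
        angles = np.zeros(3)
    rigid = RigidTransform(angles, translation, anatomy.ct.center)

    ffd = _truth_ffd(anatomy, rigid, mr_spacing_arr, mr_shape, rng, ffd_magnitude)
    truth = TransformChain(rigid, ffd)

    mr, mr_labels = _render_mr(
        anatomy, truth, mr_shape, mr_spacing_arr, rng,
        bias_amplitude, noise_level, texture_amplitude,
    )
    mr_landmarks = LandmarkSet(
        anatomy.landmarks.names, truth.apply(anatomy.landmarks.points, outside_zero=True)
    )
    return PhantomCase(
        ct=anatomy.ct,
        mr=mr,
        ct_labels=anatomy.labels,
        mr_labels=mr_labels,
        ct_landmarks=anatomy.landmarks,
        mr_landmarks=mr_landmarks,
        truth=truth,
        seed=int(seed),
    )


def generate_case(
    seed: int,
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 4.0),
    rigid_magnitude: float = 8.0,
    ffd_magnitude: float = 6.0,
    mr_shape=(48, 48, 48),
    mr_spacing=None,
    **mr_kwargs,
) -> PhantomCase:
    """One-call phantom: anatomy + random ground-truth warp + MR rendering."""
    anatomy = generate_anatomy(seed, shape, spacing)
    return warp_case(
        anatomy, seed, rigid_magnitude, ffd_magnitude, mr_shape, mr_spacing, **mr_kwargs
    )
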
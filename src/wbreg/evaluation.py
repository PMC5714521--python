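"""Registration validation metrics: landmarks, volume overlap, overlay error,
and surface distances.

Per labelled region r with source mask S (the registered/moving
segmentation brought into the fixed grid) and target mask T (the fixed
segmentation):

* target overlap        TO = |S∩T| / |T|
* Dice coefficient      DC = 2|S∩T| / (|S| + |T|)
* Jaccard coefficient   JC = |S∩T| / |S∪T|          (DC = 2·JC/(1+JC))
* false negative        FN = |T\\S| / |T|            (TO + FN = 1)
* false positive        FP = |S\\T| / |S|
* volume similarity     VS = 2(|S| - |T|) / (|S| + |T|)   (signed)

Surface measures use boundary voxels (6-connectivity face exposure, the
array border counting as outside) and a Euclidean distance transform in
physical mm:

* distance error DE: mean over source-boundary points of the minimum
  distance to the target boundary;
* Hausdorff distance HD (directed, source→target): the maximum of the
  same distances.

Landmark error is the Euclidean mm distance between paired named points,
optionally after mapping the fixed-space point through a transform chain.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, LandmarkSet, Volume, GeometryError, pair_check
from .transforms import TransformChain

__all__ = [
    "OverlapRecord",
    "SurfaceRecord",
    "MetricRecord",
    "UndefinedMetricError",
    "EmptyRegionError",
    "overlap_suite",
    "dc_from_jc",
    "agreement_category",
    "boundary_points",
    "surface_distances",
    "symmetric_hausdorff",
    "landmark_errors",
    "map_labels",
    "evaluate_case",
    "records_to_frame",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty."""


class EmptyRegionError(ValueError):
    """An operation that needs a nonempty mask received an empty one."""


@dataclass
class OverlapRecord:
    region: str
    TO: float
    DC: float
    JC: float
    FN: float
    FP: float
    VS: float
    source_voxels: int
    target_voxels: int
    intersection_voxels: int
    source_mm3: float
    target_mm3: float


@dataclass
class SurfaceRecord:
    region: str
    DE: float
    HD: float
    source_boundary_points: int
    target_boundary_points: int


@dataclass
class MetricRecord:
    """Per-region row feeding cohort statistics; NaNs where undefined."""

    region: str
    TO: float
    DC: float
    JC: float
    FN: float
    FP: float
    VS: float
    DE: float
    HD: float
    defined: bool
    note: str = ""


def overlap_suite(S: np.ndarray, T: np.ndarray, spacing, region: str = "") -> OverlapRecord:
    """All overlap and overlay-error figures by exact voxel counting."""
    S = np.asarray(S, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if S.shape != T.shape:
        raise GeometryError(f"mask shapes differ: {S.shape} vs {T.shape}")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    ns = int(np.count_nonzero(S))
    nt = int(np.count_nonzero(T))
    ni = int(np.count_nonzero(S & T))
    nu = ns + nt - ni
    if nt == 0:
        raise UndefinedMetricError(f"region {region!r}: TO/FN undefined (empty target)")
    if ns == 0:
        raise UndefinedMetricError(f"region {region!r}: FP undefined (empty source)")
    vox_mm3 = float(np.prod(spacing))
    return OverlapRecord(
        region=region,
        TO=ni / nt,
        DC=2.0 * ni / (ns + nt),
        JC=ni / nu,
        FN=(nt - ni) / nt,
        FP=(ns - ni) / ns,
        VS=2.0 * (ns - nt) / (ns + nt),
        source_voxels=ns,
        target_voxels=nt,
        intersection_voxels=ni,
        source_mm3=ns * vox_mm3,
        target_mm3=nt * vox_mm3,
    )


def dc_from_jc(jc: float) -> float:
    """Dice from Jaccard: DC = 2·JC / (1 + JC)."""
    if not 0.0 <= jc <= 1.0:
        raise ValueError(f"Jaccard coefficient must be in [0, 1], got {jc}")
    return 2.0 * jc / (1.0 + jc)


_AGREEMENT_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "excellent"),
)


def agreement_category(dc: float) -> str:
    """Qualitative agreement band for a Dice value.

    <0.2 poor, [0.2,0.4) fair, [0.4,0.6) moderate, [0.6,0.8) good,
    [0.8,1.0] excellent.  ("moderate" names the band the conventional
    list leaves unlabelled.)
    """
    if not 0.0 <= dc <= 1.0:
        raise ValueError(f"Dice coefficient must be in [0, 1], got {dc}")
    for hi, name in _AGREEMENT_BANDS:
        if dc < hi:
            return name
    return "excellent"


_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask with a face-adjacent outside (or out-of-bounds) neighbour."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACES, border_value=0)
    return mask & ~eroded


def boundary_points(mask: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(N, 3) physical centres of boundary voxels of a nonempty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("cannot extract the boundary of an empty mask")
    idx = np.argwhere(_boundary_mask(mask))
    return np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)


def surface_distances(S: np.ndarray, T: np.ndarray, spacing, region: str = "") -> SurfaceRecord:
    """Directed (source→target) boundary distances via a Euclidean distance map.

    The anisotropic voxel spacing is respected: the distance transform of
    the target boundary is computed in physical mm and sampled at the
    source-boundary voxel centres.
    """
    S = np.asarray(S, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if S.shape != T.shape:
        raise GeometryError(f"mask shapes differ: {S.shape} vs {T.shape}")
    if not S.any() or not T.any():
        raise EmptyRegionError(f"region {region!r}: empty mask in surface distance")
    sb = _boundary_mask(S)
    tb = _boundary_mask(T)
    dist_map = ndimage.distance_transform_edt(~tb, sampling=np.asarray(spacing, dtype=float))
    d = dist_map[sb]
    return SurfaceRecord(
        region=region,
        DE=float(d.mean()),
        HD=float(d.max()),
        source_boundary_points=int(sb.sum()),
        target_boundary_points=int(tb.sum()),
    )


def symmetric_hausdorff(S: np.ndarray, T: np.ndarray, spacing) -> float:
    """max(HD_{S->T}, HD_{T->S}) — the symmetrized variant of the directed HD."""
    return max(surface_distances(S, T, spacing).HD, surface_distances(T, S, spacing).HD)


def landmark_errors(
    fixed: LandmarkSet,
    moving: LandmarkSet,
    chain: TransformChain | None = None,
) -> pd.Series:
    """Per-landmark Euclidean distances (mm), indexed by landmark name.

    With a chain, the fixed-space point is mapped into the moving domain
    first (the registration-error reading); without one, raw pairwise
    distances (the pre-registration misalignment).
    """
    pair_check(fixed, moving)
    pts = fixed.points
    if chain is not None:
        pts = chain.apply(pts, outside_zero=True)
    d = np.linalg.norm(pts - moving.points, axis=1)
    return pd.Series(d, index=fixed.names, name="error_mm")


def map_labels(
    source: LabelVolume,
    chain: TransformChain | None,
    reference: Volume,
    method: str = "linear",
) -> LabelVolume:
    """Bring a label volume into the reference grid through a transform chain.

    ``method='linear'`` interpolates a per-code indicator channel linearly
    and assigns each output voxel the arg-max code (sub-voxel boundary
    placement); ``'nearest'`` is plain nearest-neighbour label pulling.
    """
    pts = reference.voxel_centers()
    if chain is not None:
        pts = chain.apply(pts, outside_zero=True)
    vox = (pts - source.origin) / source.spacing
    labels = np.asarray(source.labels)
    if method == "nearest":
        out = ndimage.map_coordinates(labels, vox.T, order=0, mode="constant", cval=0)
    elif method == "linear":
        codes = [0] + sorted(set(source.regions.values()))
        probs = np.empty((len(codes), pts.shape[0]))
        for i, code in enumerate(codes):
            probs[i] = ndimage.map_coordinates(
                (labels == code).astype(float), vox.T, order=1,
                mode="constant", cval=1.0 if code == 0 else 0.0,
            )
        out = np.array(codes, dtype=labels.dtype)[np.argmax(probs, axis=0)]
    else:
        raise ValueError(f"unknown label transfer method {method!r}")
    return LabelVolume(
        out.reshape(reference.shape).astype(labels.dtype),
        dict(source.regions),
        reference.spacing.copy(),
        reference.origin.copy(),
    )


def evaluate_case(
    fixed_labels: LabelVolume,
    source_labels: LabelVolume,
    fixed_landmarks: LandmarkSet | None = None,
    moving_landmarks: LandmarkSet | None = None,
    chain: TransformChain | None = None,
    label_transfer: str = "linear",
):
    """Full per-case evaluation: one MetricRecord per region plus a landmark table.

    ``source_labels`` live on the moving grid and are mapped into the
    fixed grid through the chain before voxel counting.  A region present
    in only one volume yields a flagged record (NaN metrics), never a
    silent omission.
    """
    reference = fixed_labels.geometry
    mapped = map_labels(source_labels, chain, reference, method=label_transfer)
    regions = sorted(set(fixed_labels.regions) | set(source_labels.regions))
    records = []
    for name in regions:
        T = fixed_labels.region_mask(name) if name in fixed_labels.regions else np.zeros(reference.shape, bool)
        S = mapped.region_mask(name) if name in mapped.regions else np.zeros(reference.shape, bool)
        if not T.any() or not S.any():
            which = "target" if not T.any() else "source"
            records.append(
                MetricRecord(name, *([np.nan] * 8), defined=False,
                             note=f"region empty in {which}")
            )
            continue
        ov = overlap_suite(S, T, fixed_labels.spacing, region=name)
        sd = surface_distances(S, T, fixed_labels.spacing, region=name)
        records.append(
            MetricRecord(name, ov.TO, ov.DC, ov.JC, ov.FN, ov.FP, ov.VS,
                         sd.DE, sd.HD, defined=True)
        )
    lm_table = None
    if fixed_landmarks is not None and moving_landmarks is not None:
        lm_table = landmark_errors(fixed_landmarks, moving_landmarks, chain)
    return records, lm_table


def records_to_frame(records, case: str | None = None) -> pd.DataFrame:
    """MetricRecords as a tidy DataFrame (one row per region)."""
    df = pd.DataFrame([asdict(r) for r in records])
    if case is not None:
        df.insert(0, "case", case)
    return df
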
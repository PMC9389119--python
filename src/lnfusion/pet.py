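"""PET metabolic quantification and CT short-axis measurement.

Works on an explicit voxel grid of tissue activity concentration (MBq/g)
plus a binary node delineation.  The standardized uptake value normalises
activity by injected dose per body weight:

    SUV = concentration (MBq/g) / [injected dose (MBq) / body weight (g)]

Metabolic tumor volume (MTV) is the volume of delineated voxels at or above
an SUV threshold (absolute SUV 2.5 by default, matching the common
PET-positivity criterion); total lesion glycolysis is TLG = SUVmean × MTV
with SUVmean taken over the MTV-qualifying voxels, so the identity holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

DEFAULT_MTV_THRESHOLD = 2.5

__all__ = [
    "DEFAULT_MTV_THRESHOLD",
    "PetVoi",
    "AcquisitionInfo",
    "PetFeatures",
    "suv_map",
    "suv_max",
    "suv_mean",
    "mtv",
    "tlg",
    "short_axis",
    "min_feret_diameter",
    "quantify",
]


@dataclass(frozen=True)
class AcquisitionInfo:
    """Tracer dose and patient mass needed to normalise activity into SUV."""

    injected_dose_mbq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be > 0")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be > 0")


@dataclass(frozen=True)
class PetVoi:
    """Voxel grid of activity concentration with an aligned node delineation."""

    activity: np.ndarray  # (nz, ny, nx) MBq/g
    voxel_mm: tuple[float, float, float]  # (dz, dy, dx)
    mask: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if act.ndim != 3:
            raise ValueError("activity grid must be 3-D")
        if mask.shape != act.shape:
            raise ValueError("mask shape must match activity grid")
        if not mask.any():
            raise ValueError("delineation mask is empty")
        if (act < 0).any():
            raise ValueError("activity concentrations must be >= 0")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel dimensions must be > 0")
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_volume_cm3(self) -> float:
        dz, dy, dx = self.voxel_mm
        return dz * dy * dx / 1000.0


@dataclass(frozen=True)
class PetFeatures:
    suv_max: float
    suv_mean: float  # over the MTV-qualifying voxels (so tlg = suv_mean * mtv)
    mtv_cm3: float
    tlg: float
    short_axis_mm: float
    suv_mean_delineation: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.mtv_cm3 > 0 and not self.suv_max >= self.suv_mean >= 0:
            raise ValueError("requires suv_max >= suv_mean >= 0")
        if self.mtv_cm3 < 0:
            raise ValueError("mtv must be >= 0")


def suv_map(voi: PetVoi, acq: AcquisitionInfo) -> np.ndarray:
    """Per-voxel SUV grid."""
    return voi.activity / (acq.injected_dose_mbq / acq.body_weight_g)


def _masked(suv: np.ndarray, mask: np.ndarray) -> np.ndarray:
    suv = np.asarray(suv, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != suv.shape:
        raise ValueError("mask shape must match SUV grid")
    vals = suv[mask]
    if vals.size == 0:
        raise ValueError("delineation mask is empty")
    return vals


def suv_max(suv: np.ndarray, mask: np.ndarray) -> float:
    return float(_masked(suv, mask).max())


def suv_mean(suv: np.ndarray, mask: np.ndarray) -> float:
    return float(_masked(suv, mask).mean())


def _mtv_select(
    suv: np.ndarray,
    mask: np.ndarray,
    threshold_mode: str,
    threshold_value: float,
) -> np.ndarray:
    if threshold_value < 0:
        raise ValueError("threshold_value must be >= 0")
    vals = _masked(suv, mask)
    if threshold_mode == "absolute":
        thr = threshold_value
    elif threshold_mode == "fraction_of_max":
        thr = threshold_value * float(vals.max())
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    # voxels exactly at threshold are included
    return vals[vals >= thr]


def mtv(
    suv: np.ndarray,
    mask: np.ndarray,
    voxel_mm: tuple[float, float, float],
    threshold_mode: str = "absolute",
    threshold_value: float = DEFAULT_MTV_THRESHOLD,
) -> float:
    """Metabolic tumor volume in cm³."""
    qualifying = _mtv_select(suv, mask, threshold_mode, threshold_value)
    dz, dy, dx = voxel_mm
    return float(qualifying.size * dz * dy * dx / 1000.0)


def tlg(
    suv: np.ndarray,
    mask: np.ndarray,
    voxel_mm: tuple[float, float, float],
    threshold_mode: str = "absolute",
    threshold_value: float = DEFAULT_MTV_THRESHOLD,
) -> float:
    """Total lesion glycolysis = SUVmean (over MTV voxels) × MTV; 0 when MTV 0."""
    qualifying = _mtv_select(suv, mask, threshold_mode, threshold_value)
    if qualifying.size == 0:
        return 0.0
    dz, dy, dx = voxel_mm
    vol = qualifying.size * dz * dy * dx / 1000.0
    return float(qualifying.mean() * vol)


def min_feret_diameter(points: np.ndarray) -> float:
    """Minimum caliper (Feret) diameter of a 2-D point set.

    The minimum width of a convex polygon is attained perpendicular to one of
    its edges, so scanning hull-edge normals is exact.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] == 1:
        return 0.0
    if uniq.shape[0] == 2 or np.linalg.matrix_rank(uniq - uniq[0]) < 2:
        # collinear: width perpendicular to the line is 0
        return 0.0
    hull = ConvexHull(uniq)
    verts = uniq[hull.vertices]
    edges = np.roll(verts, -1, axis=0) - verts
    norms = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
    norms /= np.linalg.norm(norms, axis=1, keepdims=True)
    proj = verts @ norms.T  # (n_verts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def short_axis(
    mask: np.ndarray,
    voxel_mm: tuple[float, float, float],
) -> float:
    """Node short axis in mm.

    On the axial (z) slice with the largest delineated area, the minimum
    caliper diameter of the pixel region (each pixel treated as a full
    dy × dx box, so a 20×10 px rectangle at 1 mm pitch measures 10 mm).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D (z, y, x)")
    areas = mask.sum(axis=(1, 2))
    if areas.max() == 0:
        raise ValueError("delineation mask is empty")
    z = int(np.argmax(areas))
    ys, xs = np.nonzero(mask[z])
    _, dy, dx = voxel_mm
    # pixel corner cloud: centres offset by ±half a pitch in each axis
    cy = ys[:, None] * dy + np.array([-0.5, -0.5, 0.5, 0.5]) * dy
    cx = xs[:, None] * dx + np.array([-0.5, 0.5, -0.5, 0.5]) * dx
    corners = np.stack([cy.ravel(), cx.ravel()], axis=1)
    return min_feret_diameter(corners)


def quantify(
    voi: PetVoi,
    acq: AcquisitionInfo,
    threshold_mode: str = "absolute",
    threshold_value: float = DEFAULT_MTV_THRESHOLD,
) -> PetFeatures:
    """Full PET/CT feature set for one node."""
    suv = suv_map(voi, acq)
    qualifying = _mtv_select(suv, voi.mask, threshold_mode, threshold_value)
    vol = float(qualifying.size) * voi.voxel_volume_cm3
    mean_q = float(qualifying.mean()) if qualifying.size else 0.0
    return PetFeatures(
        suv_max=suv_max(suv, voi.mask),
        suv_mean=mean_q,
        mtv_cm3=vol,
        tlg=mean_q * vol,
        short_axis_mm=short_axis(voi.mask, voi.voxel_mm),
        suv_mean_delineation=suv_mean(suv, voi.mask),
    )
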
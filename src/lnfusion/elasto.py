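"""Quantitative indicators computed from EBUS elastography stills.

An elastogram encodes relative tissue stiffness as a blue→green→red color
overlay (blue = hard, green/red = soft).  Within a node region of interest
(ROI) this module computes the indicators used for malignancy prediction:

* ``stiff_area_ratio`` (SAR) — fraction of ROI pixels in the blue (stiff) band;
* ``mean_hue`` — arithmetic mean hue on a 0–180 axis;
* ``color_ratio`` — pixel-count ratios between colormap bands (B/G, B/R);
* ``mean_gray`` — mean stiffness index (or plain luma);
* ``consensus_grade`` — the 1–5 qualitative grading score consensus.

Hue convention
--------------
Hue lives on a 0–180 axis (half the usual 0–360 degree circle).  Following
the clinical elastography literature, the *stiff* (blue) band is the closed
interval [145, 180] on this axis — note this is the literature's convention
for vendor elastography overlays, not the position of pure HSV blue (which
maps to 120 here).  The band is configurable.

Colormap
--------
The module's reference colormap has 256 entries, index 0 = deepest blue
(hue 180) through index 255 = deepest red (hue 0), linear in hue, full
saturation and value.  Under this map the RGB "color density" convention
(blue = indices 0–49) coincides with the hue convention (blue = hue
[145.4, 180]): 180 * (1 - 49/255) ≈ 145.4.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

HUE_SCALE_MAX = 180.0
#: Closed hue interval treated as stiff (blue) tissue.
DEFAULT_STIFF_BAND: tuple[float, float] = (145.0, 180.0)
#: Default colormap-index bands.  Blue is stated by the color-density
#: convention (0–49); green/red split the remainder evenly.
DEFAULT_COLOR_BANDS: dict[str, tuple[int, int]] = {
    "blue": (0, 49),
    "green": (50, 152),
    "red": (153, 255),
}

__all__ = [
    "HUE_SCALE_MAX",
    "DEFAULT_STIFF_BAND",
    "DEFAULT_COLOR_BANDS",
    "ElastoFeatures",
    "elastography_colormap",
    "hue_to_colormap_index",
    "to_hue_map",
    "stiff_area_ratio",
    "mean_hue",
    "colormap_band_masks",
    "nearest_colormap_index",
    "color_ratio",
    "mean_gray",
    "consensus_grade",
    "dichotomize_grade",
    "quantify",
]


@dataclass(frozen=True)
class ElastoFeatures:
    """Per-node elastography indicators."""

    sar: float
    bg_ratio: float
    br_ratio: float
    mean_hue: float
    mean_gray: float
    grade: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sar <= 1.0:
            raise ValueError(f"sar must be in [0,1], got {self.sar}")
        if not 0.0 <= self.mean_hue <= HUE_SCALE_MAX:
            raise ValueError(f"mean_hue must be in [0,180], got {self.mean_hue}")
        if not 0.0 <= self.mean_gray <= 255.0:
            raise ValueError(f"mean_gray must be in [0,255], got {self.mean_gray}")
        for name in ("bg_ratio", "br_ratio"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.grade is not None and self.grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"grade must be in 1..5, got {self.grade}")


def colormap_index_hue(index: np.ndarray | int) -> np.ndarray | float:
    """Hue (0–180 axis) of colormap entry ``index`` (0 = blue, 255 = red).

    Entries sit at bin centres of a 256-bin partition of the hue axis,
    index 0 → 179.65, index 255 → 0.35; the half-bin offset keeps the deep
    blue end away from the 180 ≡ 0 hue wrap so every entry has a distinct,
    recoverable hue.  Index 49 → 145.2: the blue color-density band [0, 49]
    coincides with the stiff hue band [145, 180].
    """
    return HUE_SCALE_MAX * (1.0 - (np.asarray(index) + 0.5) / 256.0)


def hue_to_colormap_index(hue: np.ndarray) -> np.ndarray:
    """Nearest colormap index for a hue value on the 0–180 axis."""
    idx = np.rint(256.0 * (1.0 - np.asarray(hue, dtype=float) / HUE_SCALE_MAX) - 0.5)
    return np.clip(idx, 0, 255).astype(np.int64)


def elastography_colormap() -> np.ndarray:
    """The reference 256×3 uint8 colormap (index 0 deep blue → 255 deep red)."""
    hue = colormap_index_hue(np.arange(256))
    hsv = np.stack(
        [hue * 2.0 / 360.0, np.ones(256), np.ones(256)], axis=-1
    )
    rgb = hsv_to_rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


_COLORMAP = elastography_colormap()
_COLORMAP_F = _COLORMAP.astype(np.float64)


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    return img


def _check_roi(roi: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.asarray(roi).astype(bool)
    if mask.shape != shape:
        raise ValueError(f"ROI shape {mask.shape} does not match image {shape}")
    if not mask.any():
        raise ValueError("ROI is empty")
    return mask


def to_hue_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel hue raster on [0, 180).

    Standard RGB→HSV hue scaled by 1/2 so the full hue circle maps onto
    [0, 180); achromatic pixels (R=G=B) get hue 0 by convention.
    """
    img = _check_image(image)
    hsv = rgb_to_hsv(img.astype(np.float64) / 255.0)
    return hsv[..., 0] * HUE_SCALE_MAX


def stiff_area_ratio(
    hue_map: np.ndarray,
    roi: np.ndarray,
    stiff_band: tuple[float, float] = DEFAULT_STIFF_BAND,
) -> float:
    """Fraction of ROI pixels whose hue lies in the closed stiff band."""
    hue = np.asarray(hue_map, dtype=float)
    mask = _check_roi(roi, hue.shape)
    lo, hi = stiff_band
    vals = hue[mask]
    return float(np.count_nonzero((vals >= lo) & (vals <= hi)) / vals.size)


def mean_hue(hue_map: np.ndarray, roi: np.ndarray) -> float:
    """Arithmetic mean hue over the ROI (no circular averaging).

    All hue values of interest sit far from the 0/180 wrap point under the
    module's convention, so a plain mean is used deliberately.
    """
    hue = np.asarray(hue_map, dtype=float)
    mask = _check_roi(roi, hue.shape)
    return float(hue[mask].mean())


def nearest_colormap_index(image: np.ndarray) -> np.ndarray:
    """Map every pixel to its nearest colormap entry (Euclidean RGB distance)."""
    img = _check_image(image).astype(np.float64)
    flat = img.reshape(-1, 3)
    out = np.empty(flat.shape[0], dtype=np.int64)
    # chunked to bound the (pixels × 256) distance matrix
    step = 65536
    cm = _COLORMAP_F
    cm_sq = (cm**2).sum(axis=1)
    for start in range(0, flat.shape[0], step):
        block = flat[start : start + step]
        # |p - c|^2 = |p|^2 - 2 p·c + |c|^2 ; |p|^2 constant per pixel
        d = cm_sq[None, :] - 2.0 * block @ cm.T
        out[start : start + step] = np.argmin(d, axis=1)
    return out.reshape(img.shape[:2])


def colormap_band_masks(
    image: np.ndarray,
    band_table: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Boolean masks assigning each pixel to a colormap-index band.

    Bands are closed intervals on the 0–255 colormap-index axis and must not
    overlap.  Defaults: blue [0, 49], green [50, 152], red [153, 255].
    """
    bands = dict(band_table) if band_table is not None else dict(DEFAULT_COLOR_BANDS)
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (na, (loa, hia)), (nb, (lob, _)) in zip(items, items[1:]):
        if hia >= lob:
            raise ValueError(f"bands {na!r} and {nb!r} overlap")
    for name, (lo, hi) in bands.items():
        if lo > hi:
            raise ValueError(f"band {name!r} has lo > hi")
    idx = nearest_colormap_index(image)
    return {name: (idx >= lo) & (idx <= hi) for name, (lo, hi) in bands.items()}


def color_ratio(
    masks: Mapping[str, np.ndarray],
    roi: np.ndarray,
    numerator: str = "blue",
    denominator: str = "green",
) -> float:
    """Pixel-count ratio between two color bands inside the ROI.

    Returns ``inf`` when the denominator band is empty but the numerator is
    not; 0.0 when both are empty.
    """
    num_mask = np.asarray(masks[numerator], dtype=bool)
    den_mask = np.asarray(masks[denominator], dtype=bool)
    mask = _check_roi(roi, num_mask.shape)
    n_num = int(np.count_nonzero(num_mask & mask))
    n_den = int(np.count_nonzero(den_mask & mask))
    if n_den == 0:
        return 0.0 if n_num == 0 else math.inf
    return n_num / n_den


def mean_gray(
    image: np.ndarray,
    roi: np.ndarray,
    mode: str = "stiffness_index",
) -> float:
    """Mean gray value over the ROI.

    ``stiffness_index`` (default): each pixel's nearest colormap index i is
    remapped to 255 − i, so deep blue (hard) scores 255 and deep red (soft)
    scores 0 — harder tissue scores higher.  ``luma``: plain Rec.601 luma
    0.299 R + 0.587 G + 0.114 B.
    """
    img = _check_image(image)
    mask = _check_roi(roi, img.shape[:2])
    if mode == "luma":
        gray = (
            0.299 * img[..., 0].astype(np.float64)
            + 0.587 * img[..., 1]
            + 0.114 * img[..., 2]
        )
    elif mode == "stiffness_index":
        gray = 255.0 - nearest_colormap_index(img).astype(np.float64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(gray[mask].mean())


def consensus_grade(final_scores: Sequence[int]) -> int:
    """Consensus of the raters' final 1–5 grading scores.

    Majority value when one exists; when all scores differ, the median.
    A rater's *final* score is their second read (the re-read supersedes).
    """
    scores = [int(s) for s in final_scores if s is not None]
    if not scores:
        raise ValueError("no grading scores provided")
    if any(s not in (1, 2, 3, 4, 5) for s in scores):
        raise ValueError(f"grading scores must be in 1..5, got {scores}")
    counts = Counter(scores)
    top, n_top = counts.most_common(1)[0]
    if n_top > 1:
        return top
    return int(np.median(scores))


def dichotomize_grade(grade: int, cutoff: int = 3) -> bool:
    """Malignant-suspicious call: grade strictly above the cutoff (default 3)."""
    return int(grade) > int(cutoff)


def quantify(
    image: np.ndarray,
    roi: np.ndarray,
    *,
    stiff_band: tuple[float, float] = DEFAULT_STIFF_BAND,
    band_table: Mapping[str, tuple[int, int]] | None = None,
    gray_mode: str = "stiffness_index",
    grade: int | None = None,
) -> ElastoFeatures:
    """Compute the full elastography indicator set for one node."""
    hue = to_hue_map(image)
    masks = colormap_band_masks(image, band_table)
    return ElastoFeatures(
        sar=stiff_area_ratio(hue, roi, stiff_band),
        bg_ratio=color_ratio(masks, roi, "blue", "green"),
        br_ratio=color_ratio(masks, roi, "blue", "red"),
        mean_hue=mean_hue(hue, roi),
        mean_gray=mean_gray(image, roi, gray_mode),
        grade=grade,
    )
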
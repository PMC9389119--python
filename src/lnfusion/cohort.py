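"""Synthetic lymph-node cohorts for exercising the pipeline end to end.

The generator draws per-node latent features (mean hue, SUVmax, grading
score, short axis) from class-conditional distributions calibrated to the
published summary statistics of intrathoracic nodes staged by PET/CT and
EBUS elastography, renders matching elastogram stills and PET uptake
volumes, and simulates a three-rater grading panel.

Two deterministic fixtures reproduce the published model-group (154 nodes)
and validation-group (53 nodes) confusion counts exactly under the default
decision cutoffs: feature values are synthetic by construction, placed a
fixed margin away from every cutoff so that only the induced calls — the
published counts — are meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import elasto
from .elasto import HUE_SCALE_MAX, elastography_colormap, hue_to_colormap_index
from .pet import AcquisitionInfo, PetVoi

MALIGNANT = "malignant"
BENIGN = "benign"

#: Model-group diagnosis composition (counts per 154 nodes).
DIAGNOSIS_COUNTS: dict[str, int] = {
    "adenocarcinoma": 42,
    "squamous_carcinoma": 18,
    "nsclc_nos": 6,
    "sclc": 16,
    "neuroendocrine_nos": 3,
    "lymphoepithelioma_like": 1,
    "unknown_lung_cancer": 2,
    "metastatic_non_lung": 4,
    "nonspecific_lymphadenitis": 52,
    "sarcoidosis": 7,
    "tuberculosis": 2,
    "ntm_infection": 1,
}

MALIGNANT_DIAGNOSES = frozenset(
    {
        "adenocarcinoma",
        "squamous_carcinoma",
        "nsclc_nos",
        "sclc",
        "neuroendocrine_nos",
        "lymphoepithelioma_like",
        "unknown_lung_cancer",
        "metastatic_non_lung",
        "lymphoma",
    }
)

BENIGN_DIAGNOSES = frozenset(
    {"nonspecific_lymphadenitis", "sarcoidosis", "tuberculosis", "ntm_infection"}
)

#: Nodal-station composition of the model group (counts per 154).
STATION_COUNTS: dict[str, int] = {
    "2R": 1, "3P": 1, "4L": 12, "4R": 47, "7": 51,
    "10L": 3, "10R": 6, "11L": 16, "11Ri": 9, "11Rs": 8,
}

#: P(grade = g | class); operating points match the published grading-score
#: sensitivity 81.52 % (P(grade > 3 | malignant)) and specificity 87.10 %.
GRADE_PMF: dict[str, tuple[float, ...]] = {
    MALIGNANT: (0.02, 0.06, 0.1048, 0.45, 0.3652),
    BENIGN: (0.30, 0.35, 0.221, 0.10, 0.029),
}

#: Class-conditional short-axis normals (mm), floored at 2 mm, calibrated so
#: P(short axis > 10 mm) matches the published size rule's sensitivity
#: (95.65 %) and 1 - specificity (79.03 %).
SHORT_AXIS_PARAMS: dict[str, tuple[float, float]] = {
    MALIGNANT: (16.0, 3.5),
    BENIGN: (13.0, 3.73),
}

__all__ = [
    "CohortConfig",
    "LymphNodeRecord",
    "RaterPanel",
    "generate_cohort",
    "cohort_frame",
    "render_elastogram",
    "render_pet_voi",
    "make_validation_fixture",
    "make_model_fixture",
    "DIAGNOSIS_COUNTS",
    "MALIGNANT_DIAGNOSES",
    "BENIGN_DIAGNOSES",
]


def _default_diagnosis_mix() -> dict[str, float]:
    total = sum(DIAGNOSIS_COUNTS.values())
    return {k: v / total for k, v in DIAGNOSIS_COUNTS.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters.

    ``hue_params`` are the class-conditional (mean, sd) of per-node mean hue
    on the 0–180 axis; ``suvmax_params`` the per-subgroup (mean, sd) of
    SUVmax — benign granulomatous subgroups (sarcoidosis, tuberculosis)
    override the short-axis size rule because they are the classic PET
    false-positive confounders.
    """

    n_nodes: int = 154
    malignant_fraction: float = 92 / 154
    diagnosis_mix: Mapping[str, float] = field(default_factory=_default_diagnosis_mix)
    hue_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {MALIGNANT: (145.00, 16.16), BENIGN: (119.66, 17.74)}
    )
    suvmax_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "short_axis_gt_1cm": (11.00, 5.36),
            "short_axis_le_1cm": (6.01, 3.53),
            "sarcoidosis": (13.53, 8.37),
            "tuberculosis": (17.57, 10.89),
        }
    )
    rater_error_p: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must be in [0,1]")
        total = sum(self.diagnosis_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"diagnosis_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.diagnosis_mix.values()):
            raise ValueError("diagnosis_mix probabilities must be >= 0")
        unknown = set(self.diagnosis_mix) - MALIGNANT_DIAGNOSES - BENIGN_DIAGNOSES
        if unknown:
            raise ValueError(f"unknown diagnoses: {sorted(unknown)}")
        for params in (self.hue_params, self.suvmax_params):
            if any(sd < 0 for _, sd in params.values()):
                raise ValueError("all sd must be >= 0")
        if not 0.0 <= self.rater_error_p <= 1.0:
            raise ValueError("rater_error_p must be in [0,1]")


@dataclass(frozen=True)
class LymphNodeRecord:
    """One simulated node with its latent (noise-free) feature values."""

    node_id: str
    patient_id: str
    station: str
    short_axis_mm: float
    true_class: str
    diagnosis: str
    latent_mean_hue: float
    latent_suvmax: float
    latent_grade: int

    def __post_init__(self) -> None:
        if self.short_axis_mm <= 0:
            raise ValueError("short_axis_mm must be > 0")
        if self.latent_grade not in (1, 2, 3, 4, 5):
            raise ValueError("latent_grade must be in 1..5")
        expected = MALIGNANT if self.diagnosis in MALIGNANT_DIAGNOSES else BENIGN
        if self.true_class != expected:
            raise ValueError(
                f"true_class {self.true_class!r} inconsistent with diagnosis "
                f"{self.diagnosis!r}"
            )


@dataclass(frozen=True)
class RaterPanel:
    """Scores of 3 raters × 2 reads per node (long-format table)."""

    scores: pd.DataFrame  # columns: node_id, rater, read, score
    error_p: float

    def final_scores(self, node_id: str) -> list[int]:
        """Each rater's final score is their second read."""
        sub = self.scores[(self.scores["node_id"] == node_id) & (self.scores["read"] == 2)]
        return sub.sort_values("rater")["score"].astype(int).tolist()

    def consensus(self, node_id: str) -> int:
        return elasto.consensus_grade(self.final_scores(node_id))


@lru_cache(maxsize=256)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a truncated normal whose truncated mean is ``mean``.

    The printed summaries are treated as the mean/sd targets of the truncated
    law; with a naive location = mean the truncation would bias large-sample
    means visibly (≈ -0.6 hue units for the malignant hue distribution).
    """
    if sd == 0:
        return mean

    def f(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    span = 8 * sd
    return float(brentq(f, mean - span, mean + span, xtol=1e-10))


def _sample_truncated(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    loc = _matched_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_cohort(config: CohortConfig) -> tuple[list[LymphNodeRecord], RaterPanel]:
    """Draw a cohort of nodes plus a simulated grading-panel table.

    Deterministic given ``config.seed``.  With ``stratified=True`` the
    malignant count is exactly ``round(n * malignant_fraction)`` and
    per-class diagnosis counts follow largest-remainder allocation, so the
    default 154-node configuration reproduces the published composition
    exactly (92 malignant, 42 adenocarcinoma, ...).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    if n == 0:
        empty = pd.DataFrame(columns=["node_id", "rater", "read", "score"])
        return [], RaterPanel(scores=empty, error_p=config.rater_error_p)

    mal_labels = [d for d in config.diagnosis_mix if d in MALIGNANT_DIAGNOSES]
    ben_labels = [d for d in config.diagnosis_mix if d in BENIGN_DIAGNOSES]
    mal_w = np.array([config.diagnosis_mix[d] for d in mal_labels], dtype=float)
    ben_w = np.array([config.diagnosis_mix[d] for d in ben_labels], dtype=float)

    if config.stratified:
        n_mal = int(round(n * config.malignant_fraction))
        diagnoses: list[str] = []
        for labels, w, total in ((mal_labels, mal_w, n_mal), (ben_labels, ben_w, n - n_mal)):
            counts = _largest_remainder(w, total)
            for lab, c in zip(labels, counts):
                diagnoses.extend([lab] * int(c))
    else:
        classes = rng.random(n) < config.malignant_fraction
        diagnoses = []
        for is_mal in classes:
            labels, w = (mal_labels, mal_w) if is_mal else (ben_labels, ben_w)
            if len(labels) == 0:
                raise ValueError("diagnosis_mix has no labels for a sampled class")
            diagnoses.append(rng.choice(labels, p=w / w.sum()))
    rng.shuffle(diagnoses)

    stations = list(STATION_COUNTS)
    station_p = np.array(list(STATION_COUNTS.values()), dtype=float)
    station_p /= station_p.sum()

    records: list[LymphNodeRecord] = []
    panel_rows: list[tuple[str, int, int, int]] = []
    for i, diag in enumerate(diagnoses):
        cls = MALIGNANT if diag in MALIGNANT_DIAGNOSES else BENIGN
        sa_mean, sa_sd = SHORT_AXIS_PARAMS[cls]
        short_axis = float(_sample_truncated(rng, sa_mean, sa_sd, 2.0, np.inf, 1)[0])
        hmean, hsd = config.hue_params[cls]
        hue = float(_sample_truncated(rng, hmean, hsd, 0.0, HUE_SCALE_MAX, 1)[0])
        if diag in config.suvmax_params:
            smean, ssd = config.suvmax_params[diag]
        elif short_axis > 10.0:
            smean, ssd = config.suvmax_params["short_axis_gt_1cm"]
        else:
            smean, ssd = config.suvmax_params["short_axis_le_1cm"]
        suv = float(_sample_truncated(rng, smean, ssd, 0.0, np.inf, 1)[0])
        grade = int(rng.choice(np.arange(1, 6), p=GRADE_PMF[cls]))
        node_id = f"LN{i:04d}"
        records.append(
            LymphNodeRecord(
                node_id=node_id,
                patient_id=f"P{i // 2:04d}",
                station=str(rng.choice(stations, p=station_p)),
                short_axis_mm=short_axis,
                true_class=cls,
                diagnosis=diag,
                latent_mean_hue=hue,
                latent_suvmax=suv,
                latent_grade=grade,
            )
        )
        for rater in (1, 2, 3):
            for read in (1, 2):
                score = grade
                if rng.random() < config.rater_error_p:
                    score = int(np.clip(grade + rng.choice([-1, 1]), 1, 5))
                panel_rows.append((node_id, rater, read, score))

    panel = RaterPanel(
        scores=pd.DataFrame(panel_rows, columns=["node_id", "rater", "read", "score"]),
        error_p=config.rater_error_p,
    )
    return records, panel


def cohort_frame(records: Sequence[LymphNodeRecord]) -> pd.DataFrame:
    """Cohort table with one row per node."""
    cols = [
        "node_id", "patient_id", "station", "short_axis_mm", "true_class",
        "diagnosis", "latent_mean_hue", "latent_suvmax", "latent_grade",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def _record_rng(record: LymphNodeRecord, salt: str) -> np.random.Generator:
    # stable per-node default stream so rendering is reproducible on its own
    key = zlib.crc32(f"{salt}:{record.node_id}".encode())
    return np.random.default_rng(key)


def _ellipse_mask(height: int, width: int) -> np.ndarray:
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ay, ax = 0.33 * height, 0.40 * width  # ROI area ≈ 41 % of the frame
    yy, xx = np.mgrid[0:height, 0:width]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _match_mean(values: np.ndarray, target: float, lo: float, hi: float) -> np.ndarray:
    """Shift-and-clip until the sample mean hits ``target`` (when feasible)."""
    v = values.copy()
    for _ in range(40):
        delta = target - v.mean()
        if abs(delta) < 1e-3:
            break
        v = np.clip(v + delta, lo, hi)
    return v


def render_elastogram(
    record: LymphNodeRecord,
    width: int = 64,
    height: int = 64,
    target_sar: float | None = None,
    noise_sd: float = 18.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an RGB elastogram still plus its elliptical ROI mask.

    ROI pixel hues are drawn around ``record.latent_mean_hue`` and
    mean-corrected so the quantified ROI mean hue recovers the latent value
    within ±1 hue unit.  When ``target_sar`` is given, exactly
    ``round(target_sar * n_roi)`` ROI pixels are placed in the stiff band
    (sampled well inside [148, 178]) and the rest below it; the soft-pixel
    mean is then steered toward the latent mean where jointly feasible.
    Colors come from the module's documented blue→red colormap; the
    background is neutral dark gray.
    """
    if width < 32 or height < 32:
        raise ValueError("frame must be at least 32×32")
    if target_sar is not None and not 0.0 <= target_sar <= 1.0:
        raise ValueError("target_sar must be in [0,1]")
    if rng is None:
        rng = _record_rng(record, "elasto")

    mask = _ellipse_mask(height, width)
    n = int(mask.sum())
    latent = float(record.latent_mean_hue)

    if target_sar is None:
        hues = rng.normal(latent, noise_sd, size=n)
        hues = _match_mean(hues, latent, 0.0, HUE_SCALE_MAX)
    else:
        k = int(round(target_sar * n))
        stiff = rng.uniform(148.0, 178.0, size=k)
        if k < n:
            if k:
                soft_target = (n * latent - stiff.sum()) / (n - k)
            else:
                soft_target = latent
            soft_target = float(np.clip(soft_target, 5.0, 140.0))
            soft = rng.normal(soft_target, 6.0, size=n - k)
            soft = _match_mean(soft, soft_target, 2.0, 143.0)
        else:
            soft = np.empty(0)
        hues = np.concatenate([stiff, soft])
        hues = hues[rng.permutation(n)]

    cmap = elastography_colormap()
    roi_rgb = cmap[hue_to_colormap_index(hues)]
    image = np.full((height, width, 3), 40, dtype=np.uint8)
    image[mask] = roi_rgb
    return image, mask


def render_pet_voi(
    record: LymphNodeRecord,
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    dose_mbq: float = 370.0,
    weight_g: float = 70000.0,
    background_suv: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[PetVoi, AcquisitionInfo]:
    """Build a PET uptake volume whose computed SUVmax is the latent value.

    The node is an ellipsoid (short axis = ``record.short_axis_mm`` along y,
    long axis 1.6× along x, 1.3× along z) on a low-uptake background.  Uptake
    falls off radially inside the node and the centre voxel is set exactly to
    the latent SUVmax, so the peak placement is deterministic.
    """
    if dose_mbq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be > 0")
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("voxel dimensions must be > 0")
    if rng is None:
        rng = _record_rng(record, "pet")

    dz, dy, dx = voxel_mm
    sy = record.short_axis_mm / 2.0
    sx = 0.8 * record.short_axis_mm
    sz = 0.65 * record.short_axis_mm
    nz = max(5, int(np.ceil(2 * sz / dz)) + 4)
    ny = max(5, int(np.ceil(2 * sy / dy)) + 4)
    nx = max(5, int(np.ceil(2 * sx / dx)) + 4)
    nz += 1 - nz % 2  # odd dims so a voxel centre sits exactly at the node centre
    ny += 1 - ny % 2
    nx += 1 - nx % 2

    zc, yc, xc = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    r2 = (
        ((zz - zc) * dz / sz) ** 2
        + ((yy - yc) * dy / sy) ** 2
        + ((xx - xc) * dx / sx) ** 2
    )
    mask = r2 <= 1.0

    k = dose_mbq / weight_g  # MBq/g per SUV unit
    suv = background_suv * (0.8 + 0.4 * rng.random((nz, ny, nx)))
    inside = record.latent_suvmax * (0.30 + 0.60 * (1.0 - r2[mask]))
    suv[mask] = inside
    suv[int(zc), int(yc), int(xc)] = record.latent_suvmax  # exact peak
    voi = PetVoi(activity=suv * k, voxel_mm=voxel_mm, mask=mask)
    return voi, AcquisitionInfo(injected_dose_mbq=dose_mbq, body_weight_g=weight_g)


# ---------------------------------------------------------------------------
# Deterministic fixtures reproducing the published confusion counts.
#
# Feature values are placed ≥ 10 % away from every default cutoff
# (SUVmax 7.02, TLG 12.53, hue 132.73, grade 3) so boundary-handling changes
# cannot flip a call; OR-arms are exercised by alternating which feature
# triggers a positive component call.
# ---------------------------------------------------------------------------

_POS_SUV, _NEG_SUV = 8.2, 6.1  # cutoff 7.02: >7.73 / <6.32
_POS_TLG, _NEG_TLG = 15.5, 11.0  # cutoff 12.53: >13.79 / <11.27
_POS_HUE, _NEG_HUE = 150.0, 117.0  # cutoff 132.73: >146.01 / <119.45
_POS_GRADE, _NEG_GRADE = 4, 2


def _fixture_rows(
    cells: Sequence[tuple[bool, bool, str, str]],
    group: str,
) -> pd.DataFrame:
    """Build fixture rows from (petct_call, elasto_call, class, diagnosis)."""
    rows = []
    for i, (pet_pos, ela_pos, cls, diag) in enumerate(cells):
        if pet_pos:
            if i % 2 == 0:  # both PET arms positive
                suv, tlg_v = _POS_SUV + 0.05 * (i % 4), _POS_TLG + 0.1 * (i % 4)
            else:  # TLG arm alone carries the call
                suv, tlg_v = _NEG_SUV, _POS_TLG + 0.1 * (i % 4)
        else:
            suv, tlg_v = _NEG_SUV - 0.05 * (i % 4), _NEG_TLG - 0.1 * (i % 4)
        if ela_pos:
            if i % 2 == 0:  # hue arm alone carries the call
                hue, grade = _POS_HUE + 0.2 * (i % 4), _NEG_GRADE
            else:  # grade arm alone
                hue, grade = _NEG_HUE, _POS_GRADE + (i % 2 and i % 3 == 0)
        else:
            hue = _NEG_HUE - 0.2 * (i % 4)
            grade = _NEG_GRADE + (i % 3 == 0)  # grade 2 or 3, both negative
        rows.append(
            {
                "node_id": f"{group}{i:04d}",
                "patient_id": f"{group}P{i:04d}",
                "station": ["4R", "7", "4L", "11L", "10R"][i % 5],
                "short_axis_mm": 15.0 if cls == MALIGNANT else 12.0,
                "true_class": cls,
                "diagnosis": diag,
                "suv_max": round(suv, 4),
                "tlg": round(tlg_v, 4),
                "mean_hue": round(hue, 4),
                "grade": int(grade),
            }
        )
    return pd.DataFrame(rows)


def _expand(joint: Sequence[tuple[bool, bool, str, Sequence[tuple[str, int]]]]):
    cells = []
    for pet_pos, ela_pos, cls, diags in joint:
        for diag, count in diags:
            cells.extend([(pet_pos, ela_pos, cls, diag)] * count)
    return cells


def make_validation_fixture() -> pd.DataFrame:
    """53-node validation cohort (36 malignant / 17 benign).

    Under the default cutoffs the induced confusion counts are exactly the
    published ones: PET/CT FP=13 FN=0, elastography FP=5 FN=2, combined
    FP=4 FN=2.  The two elastography false negatives are the published
    neuroendocrine tumor and adenocarcinoma cases; the PET false positives
    split into 8 nonspecific lymphadenitis, 3 sarcoidosis and 2 tuberculosis
    with 9 of the 13 elastography-negative.
    """
    joint = [
        # (petct_call, elasto_call, class, [(diagnosis, count), ...])
        (True, True, MALIGNANT, [
            ("adenocarcinoma", 17), ("squamous_carcinoma", 6), ("nsclc_nos", 1),
            ("sclc", 5), ("neuroendocrine_nos", 2), ("unknown_lung_cancer", 2),
            ("lymphoma", 1),
        ]),  # 34 combined true positives
        (True, False, MALIGNANT, [("neuroendocrine_nos", 1), ("adenocarcinoma", 1)]),
        (True, True, BENIGN, [
            ("nonspecific_lymphadenitis", 2), ("sarcoidosis", 1), ("tuberculosis", 1),
        ]),  # 4 combined false positives
        (True, False, BENIGN, [
            ("nonspecific_lymphadenitis", 6), ("sarcoidosis", 2), ("tuberculosis", 1),
        ]),  # rescued by elastography
        (False, True, BENIGN, [("nonspecific_lymphadenitis", 1)]),
        (False, False, BENIGN, [("nonspecific_lymphadenitis", 3)]),
    ]
    return _fixture_rows(_expand(joint), group="V")


def make_model_fixture() -> pd.DataFrame:
    """154-node model cohort (92 malignant / 62 benign).

    Forced per-method counts: PET/CT TP=86 FP=26 FN=6 TN=36; elastography
    TP=82 FP=12 FN=10 TN=50; combined TP=79 FP=7 FN=13 TN=55.  The 26 PET
    false positives break down as published (19 nonspecific lymphadenitis,
    4 sarcoidosis, 2 tuberculosis, 1 NTM) and 19 of them are
    elastography-negative.
    """
    joint = [
        (True, True, MALIGNANT, [
            ("adenocarcinoma", 36), ("squamous_carcinoma", 16), ("nsclc_nos", 5),
            ("sclc", 14), ("neuroendocrine_nos", 2), ("lymphoepithelioma_like", 1),
            ("unknown_lung_cancer", 2), ("metastatic_non_lung", 3),
        ]),  # 79
        (True, False, MALIGNANT, [
            ("adenocarcinoma", 3), ("sclc", 2), ("neuroendocrine_nos", 1),
            ("metastatic_non_lung", 1),
        ]),  # 7
        (False, True, MALIGNANT, [("adenocarcinoma", 2), ("squamous_carcinoma", 1)]),
        (False, False, MALIGNANT, [("adenocarcinoma", 1), ("squamous_carcinoma", 1), ("nsclc_nos", 1)]),
        (True, True, BENIGN, [
            ("nonspecific_lymphadenitis", 5), ("sarcoidosis", 1), ("tuberculosis", 1),
        ]),  # 7 combined false positives
        (True, False, BENIGN, [
            ("nonspecific_lymphadenitis", 14), ("sarcoidosis", 3), ("tuberculosis", 1),
            ("ntm_infection", 1),
        ]),  # 19 rescued by elastography
        (False, True, BENIGN, [("nonspecific_lymphadenitis", 5)]),
        (False, False, BENIGN, [("nonspecific_lymphadenitis", 28), ("sarcoidosis", 3)]),
    ]
    return _fixture_rows(_expand(joint), group="M")
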
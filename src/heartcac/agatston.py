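"""Rule-based coronary calcium extraction and Agatston scoring.

This is the deterministic, explainable half of the pipeline: calcium is
anything at or above 130 HU; lesions are 3D connected components
(26-connectivity); each lesion is scored slice by slice as
``area(mm^2) x density cofactor x (dz / 3.0)`` where the cofactor is 1, 2,
3 or 4 for peak slice HU in [130, 200), [200, 300), [300, 400) and >= 400;
slice components below 1 mm^2 are dropped.  Vessel attribution is a
majority vote of the lesion's voxels over a heart territory label map, and
lesions whose majority falls in the non-coronary region (or outside the
heart) are excluded from the score rather than counted — that exclusion is
the pipeline's false-positive rejection mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import CTVolume, RegionLabelMap, VESSEL_CODES, require_alignment

CALCIUM_THRESHOLD_HU = 130.0
MIN_COMPONENT_AREA_MM2 = 1.0
REFERENCE_SLICE_THICKNESS_MM = 3.0

#: Risk-category upper edges for the continuous Agatston total.
CATEGORY_EDGES = (1.0, 10.0, 100.0, 400.0)


@dataclass
class SliceComponent:
    slice_index: int
    area_mm2: float
    peak_hu: float
    cofactor: int


@dataclass
class CalciumLesion:
    lesion_id: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) coordinates
    slice_components: list[SliceComponent] = field(default_factory=list)
    vessel: int | None = None  # 1..4 coronary, 5/0 treated as non-coronary
    score: float = 0.0

    @property
    def is_coronary(self) -> bool:
        return self.vessel in VESSEL_CODES


@dataclass
class CacReport:
    """Per-vessel and total Agatston scores for one scan."""

    per_vessel: dict[str, float]
    total: float
    excluded_noncoronary: float
    risk_category: int
    lesions: list[CalciumLesion] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_vessel": dict(self.per_vessel),
            "total": self.total,
            "excluded_noncoronary": self.excluded_noncoronary,
            "risk_category": self.risk_category,
            "n_lesions": len(self.lesions),
        }


VESSEL_NAMES = {1: "LM", 2: "LAD", 3: "LCX", 4: "RCA"}


def threshold_calcium(ct: CTVolume) -> np.ndarray:
    """Binary calcium candidate mask: HU >= 130 (inclusive threshold)."""
    return ct.voxels >= CALCIUM_THRESHOLD_HU


def cofactor(peak_hu: float) -> int:
    """Agatston density weight from a slice component's peak HU."""
    if peak_hu < CALCIUM_THRESHOLD_HU:
        raise ValueError(f"peak HU {peak_hu} below calcium threshold")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


_STRUCT_3D_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_2D_8 = np.ones((3, 3), dtype=bool)


def extract_lesions(
    calc_mask: np.ndarray,
    spacing: tuple[float, float, float],
    ct_voxels: np.ndarray | None = None,
    min_area_mm2: float = MIN_COMPONENT_AREA_MM2,
) -> list[CalciumLesion]:
    """Group candidate voxels into lesions and their per-slice components.

    Lesion identity uses 26-connectivity in 3D; within each lesion, each
    axial slice is split into 8-connected 2D components whose area is
    ``n_pixels * dy * dx``.  Components under ``min_area_mm2`` are dropped,
    and lesions left with no components are dropped entirely.
    """
    _, dy, dx = spacing
    pixel_area = dy * dx
    labelled, n = ndimage.label(calc_mask, structure=_STRUCT_3D_26)
    lesions: list[CalciumLesion] = []
    for lab in range(1, n + 1):
        comp = labelled == lab
        coords = np.argwhere(comp)
        slice_components: list[SliceComponent] = []
        for z in np.unique(coords[:, 0]):
            plane = comp[z]
            sub, m = ndimage.label(plane, structure=_STRUCT_2D_8)
            for s in range(1, m + 1):
                pix = sub == s
                area = float(pix.sum()) * pixel_area
                if area < min_area_mm2:
                    continue
                if ct_voxels is not None:
                    peak = float(ct_voxels[z][pix].max())
                else:
                    peak = float("nan")
                slice_components.append(SliceComponent(int(z), area, peak, 0))
        if not slice_components:
            continue
        lesions.append(CalciumLesion(lesion_id=len(lesions) + 1, voxels=coords,
                                     slice_components=slice_components))
    return lesions


def score_lesion(lesion: CalciumLesion, spacing: tuple[float, float, float]) -> float:
    """Agatston score of one lesion: sum of area x cofactor x (dz/3)."""
    dz = spacing[0]
    thickness_factor = dz / REFERENCE_SLICE_THICKNESS_MM
    if abs(thickness_factor - 1.0) > 1e-9:
        warnings.warn(
            f"slice thickness {dz} mm differs from the 3.0 mm reference; "
            f"applying thickness factor {thickness_factor:.3f}",
            stacklevel=2,
        )
    total = 0.0
    for sc in lesion.slice_components:
        sc.cofactor = cofactor(sc.peak_hu)
        total += sc.area_mm2 * sc.cofactor * thickness_factor
    lesion.score = total
    return total


#: Tie-break priority for split lesions: LM > LAD > LCX > RCA > other/outside.
_VOTE_PRIORITY = (1, 2, 3, 4, 5, 0)


def assign_vessel(lesion: CalciumLesion, labels: RegionLabelMap) -> int:
    """Majority-vote territory of a lesion's voxels, with fixed tie-break."""
    codes = labels.voxels[lesion.voxels[:, 0], lesion.voxels[:, 1], lesion.voxels[:, 2]]
    counts = np.bincount(codes, minlength=6)
    best = max(_VOTE_PRIORITY, key=lambda c: (counts[c], -_VOTE_PRIORITY.index(c)))
    lesion.vessel = int(best)
    return lesion.vessel


def categorize(total: float) -> int:
    """Risk category of a total score: <1, 1-10, 10-100, 100-400, >400."""
    if total < 0:
        raise ValueError("Agatston total cannot be negative")
    for cat, edge in enumerate(CATEGORY_EDGES):
        if cat == 0:
            if total < edge:
                return 0
        elif total <= edge:
            return cat
    return 4


def score_scan(ct: CTVolume, labels: RegionLabelMap) -> CacReport:
    """Full deterministic scoring of one scan against a territory map."""
    require_alignment(ct, labels)
    mask = threshold_calcium(ct)
    lesions = extract_lesions(mask, ct.spacing, ct_voxels=ct.voxels)
    per_vessel = {name: 0.0 for name in VESSEL_NAMES.values()}
    excluded = 0.0
    for lesion in lesions:
        score_lesion(lesion, ct.spacing)
        assign_vessel(lesion, labels)
        if lesion.is_coronary:
            per_vessel[VESSEL_NAMES[lesion.vessel]] += lesion.score
        else:
            excluded += lesion.score
    total = float(sum(per_vessel.values()))
    return CacReport(
        per_vessel=per_vessel,
        total=total,
        excluded_noncoronary=float(excluded),
        risk_category=categorize(total),
        lesions=lesions,
    )
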
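"""Seeded synthetic gated-CCT phantoms with known ground truth.

A phantom is an ellipsoidal "heart" embedded in a mediastinum/lung
background, with four parametric coronary courses (LM, LAD, LCX, RCA)
rendered as thin bright tubes, calcific lesions as HU plateaus on those
courses, and non-coronary calcified distractors drawn from the failure
taxonomy a CAC pipeline must survive: aortic wall, mitral annulus,
pericardial plaque, mediastinal lymph node, pulmonary trunk.

Ground-truth perfusion territories partition the heart by
nearest-coronary-course distance (in mm) within a capture radius;
the remainder is the non-coronary "other" region.  The ground-truth
Agatston report for a phantom is *computed*, not asserted: the scoring
engine is run on the noiseless rendering with the true territory map.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import agatston
from .io_volumes import CTVolume, HeartMask, RegionLabelMap

# Normalized heart-frame coordinates (z, y, x), unit ball = heart ellipsoid.
# z grows caudally, y grows posteriorly, x grows toward the patient's left.
DEFAULT_VESSEL_CURVES: dict[int, tuple[tuple[float, float, float], ...]] = {
    1: ((-0.55, -0.22, 0.02), (-0.45, -0.28, 0.12)),                       # LM
    2: ((-0.45, -0.28, 0.12), (0.0, -0.70, 0.20), (0.60, -0.50, 0.10)),    # LAD
    3: ((-0.45, -0.28, 0.12), (-0.10, -0.20, 0.70), (0.30, 0.20, 0.60)),   # LCX
    4: ((-0.50, -0.25, -0.30), (0.00, -0.10, -0.75), (0.55, 0.30, -0.40)), # RCA
}

#: Distractor kinds and default normalized positions / sizes / HU.
DEFAULT_DISTRACTOR_GEOMETRY = {
    "aortic": ((-0.05, 0.12, -0.02), 7.0, 500.0),
    "mitral": ((0.25, 0.30, 0.10), 7.0, 400.0),
    "pericardial": ((0.10, 0.85, 0.00), 7.0, 350.0),
    "lymph_node": ((-0.40, -1.05, 0.20), 5.0, 300.0),
    "pulmonary": ((-0.90, -0.70, -0.20), 6.0, 350.0),
}

DISTRACTOR_KINDS = tuple(DEFAULT_DISTRACTOR_GEOMETRY)


@dataclass(frozen=True)
class Lesion:
    vessel: int          # 1..4
    t: float             # position parameter along the vessel course
    radius_mm: float
    hu: float            # plateau HU, >= 130


@dataclass(frozen=True)
class Distractor:
    kind: str
    center: tuple[float, float, float]  # normalized heart-frame coords
    radius_mm: float
    hu: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 0.7, 0.7)
    heart_center_mm: tuple[float, float, float] | None = None  # default: volume centre
    heart_semiaxes_mm: tuple[float, float, float] = (42.0, 25.0, 25.0)
    vessels: dict[int, tuple] = field(default_factory=lambda: dict(DEFAULT_VESSEL_CURVES))
    lesions: tuple[Lesion, ...] = ()
    distractors: tuple[Distractor, ...] = ()
    capture_radius_mm: float = 13.0
    blood_pool_scale: float = 0.42
    mediastinum_scale: float = 1.30
    vessel_tube_radius_mm: float = 1.0
    tissue_hu: dict = field(default_factory=lambda: {
        "lung": -800.0, "soft_tissue": 40.0, "blood_pool": 45.0,
        "myocardium": 0.0, "vessel": 50.0,
    })
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            if les.hu < agatston.CALCIUM_THRESHOLD_HU:
                raise ValueError(f"lesion plateau {les.hu} HU below calcium threshold")
            if les.vessel not in self.vessels:
                raise ValueError(f"lesion references unknown vessel {les.vessel}")

    @property
    def center_mm(self) -> np.ndarray:
        if self.heart_center_mm is not None:
            return np.asarray(self.heart_center_mm, dtype=float)
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0


@dataclass
class PhantomScan:
    spec: PhantomSpec
    ct: CTVolume
    heart: HeartMask
    territories: RegionLabelMap
    lesion_table: list[dict]
    truth_report: agatston.CacReport


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _densify(points: np.ndarray, n: int = 120) -> np.ndarray:
    """Piecewise-linear resampling of a polyline to n points."""
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return np.repeat(points, n, axis=0)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(t, cum, points[:, k]) for k in range(3)])


def _curve_mm(spec: PhantomSpec, code: int, n: int = 120) -> np.ndarray:
    """Vessel course sampled in absolute mm coordinates."""
    pts = np.asarray(spec.vessels[code], dtype=float)
    mm = spec.center_mm + pts * np.asarray(spec.heart_semiaxes_mm)
    return _densify(mm, n)


def curve_point_mm(spec: PhantomSpec, code: int, t: float) -> np.ndarray:
    """Point at arclength fraction t in [0, 1] along a vessel course."""
    dense = _curve_mm(spec, code, n=400)
    idx = int(round(t * (len(dense) - 1)))
    return dense[idx]


def _voxel_coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _ellipsoid_norm2(spec: PhantomSpec, coords, scale: float = 1.0) -> np.ndarray:
    c = spec.center_mm
    ax = np.asarray(spec.heart_semiaxes_mm) * scale
    return sum(((g - ci) / ai) ** 2 for g, ci, ai in zip(coords, c, ax))


# ---------------------------------------------------------------------------
# territories
# ---------------------------------------------------------------------------

def build_territories(spec: PhantomSpec) -> tuple[RegionLabelMap, HeartMask]:
    """Partition the heart into LM/LAD/LCX/RCA territories plus 'other'.

    Each heart voxel within the capture radius of some vessel course is
    assigned to the nearest course (Euclidean, in mm); the remainder of
    the heart is coded 5 (other); everything outside the ellipsoid is 0.
    The central blood pool (chambers/aorta) is always part of the
    non-coronary 'other' region, whatever its distance to a course — the
    coronary courses themselves must run outside it.
    """
    coords = _voxel_coords_mm(spec)
    heart = _ellipsoid_norm2(spec, coords) <= 1.0

    pts, tags = [], []
    semi = np.asarray(spec.heart_semiaxes_mm)
    for code in sorted(spec.vessels):
        dense = _curve_mm(spec, code)
        norm2 = np.sum(((dense - spec.center_mm) / semi) ** 2, axis=1)
        if np.any(norm2 > 1.0):
            raise ValueError(f"vessel {code} course leaves the heart ellipsoid")
        bp2 = np.sum(((dense - spec.center_mm) / (semi * spec.blood_pool_scale)) ** 2, axis=1)
        if np.any(bp2 <= 1.0):
            raise ValueError(f"vessel {code} course enters the blood pool")
        pts.append(dense)
        tags.append(np.full(len(dense), code))
    tree = cKDTree(np.concatenate(pts))
    tags = np.concatenate(tags)

    labels = np.zeros(spec.shape, dtype=np.int16)
    hv = np.argwhere(heart)
    hv_mm = hv * np.asarray(spec.spacing)
    dist, idx = tree.query(hv_mm)
    code = np.where(dist <= spec.capture_radius_mm, tags[idx], 5)
    labels[hv[:, 0], hv[:, 1], hv[:, 2]] = code
    labels[(_ellipsoid_norm2(spec, coords, spec.blood_pool_scale) <= 1.0) & heart] = 5

    label_map = RegionLabelMap(labels, spec.spacing)
    mask = HeartMask(heart.astype(np.uint8), spec.spacing)

    for d in spec.distractors:
        c_mm = spec.center_mm + np.asarray(d.center) * np.asarray(spec.heart_semiaxes_mm)
        vox = np.clip(np.round(c_mm / np.asarray(spec.spacing)).astype(int), 0,
                      np.asarray(spec.shape) - 1)
        if labels[tuple(vox)] in (1, 2, 3, 4):
            raise ValueError(f"distractor {d.kind!r} centre falls inside a coronary territory")
        # the whole calcification must stay majority non-coronary, with margin
        probe = np.zeros(spec.shape, dtype=np.float64)
        _paint_sphere(probe, spec, c_mm, d.radius_mm, 1.0)
        sphere = probe > 0
        frac = np.isin(labels[sphere], (1, 2, 3, 4)).mean() if sphere.any() else 0.0
        if frac >= 0.4:
            raise ValueError(
                f"distractor {d.kind!r}: {frac:.0%} of its voxels fall in coronary territories")
    return label_map, mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_sphere(vol: np.ndarray, spec: PhantomSpec, center_mm: np.ndarray,
                  radius_mm: float, hu: float) -> None:
    sp = np.asarray(spec.spacing)
    lo = np.maximum(np.floor((center_mm - radius_mm) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + radius_mm) / sp).astype(int) + 1,
                    np.asarray(spec.shape))
    if np.any(lo >= hi):
        return
    sub = [np.arange(lo[k], hi[k]) * sp[k] - center_mm[k] for k in range(3)]
    gz, gy, gx = np.meshgrid(*sub, indexing="ij")
    inside = gz * gz + gy * gy + gx * gx <= radius_mm * radius_mm
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside] = hu


def render_ct(spec: PhantomSpec, territories: RegionLabelMap | None = None,
              heart: HeartMask | None = None) -> CTVolume:
    """Render the phantom CT in HU; bit-identical for identical specs."""
    if territories is None or heart is None:
        territories, heart = build_territories(spec)
    coords = _voxel_coords_mm(spec)
    hu = spec.tissue_hu
    vol = np.full(spec.shape, hu["lung"], dtype=np.float64)
    vol[_ellipsoid_norm2(spec, coords, spec.mediastinum_scale) <= 1.0] = hu["soft_tissue"]
    inside = heart.voxels.astype(bool)
    vol[inside] = hu["myocardium"]
    vol[_ellipsoid_norm2(spec, coords, spec.blood_pool_scale) <= 1.0] = hu["blood_pool"]

    # thin bright coronary tubes along each course
    hv = np.argwhere(inside)
    hv_mm = hv * np.asarray(spec.spacing)
    pts = np.concatenate([_curve_mm(spec, c) for c in sorted(spec.vessels)])
    dist, _ = cKDTree(pts).query(hv_mm)
    tube = hv[dist <= spec.vessel_tube_radius_mm]
    vol[tube[:, 0], tube[:, 1], tube[:, 2]] = hu["vessel"]

    for les in spec.lesions:
        _paint_sphere(vol, spec, curve_point_mm(spec, les.vessel, les.t), les.radius_mm, les.hu)
    for d in spec.distractors:
        c_mm = spec.center_mm + np.asarray(d.center) * np.asarray(spec.heart_semiaxes_mm)
        _paint_sphere(vol, spec, c_mm, d.radius_mm, d.hu)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    vol = np.clip(vol, -2000.0, 4000.0)
    return CTVolume(vol.astype(np.float32), spec.spacing)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def ground_truth_report(spec: PhantomSpec,
                        territories: RegionLabelMap | None = None,
                        heart: HeartMask | None = None
                        ) -> tuple[agatston.CacReport, list[dict]]:
    """Oracle report: score the noiseless rendering with true territories."""
    if territories is None or heart is None:
        territories, heart = build_territories(spec)
    clean = render_ct(replace(spec, noise_sigma=0.0), territories, heart)
    report = agatston.score_scan(clean, territories)
    table = [
        {
            "lesion_id": les.lesion_id,
            "vessel_code": les.vessel,
            "vessel": agatston.VESSEL_NAMES.get(les.vessel, "noncoronary"),
            "coronary": les.is_coronary,
            "score": les.score,
            "n_voxels": int(len(les.voxels)),
        }
        for les in report.lesions
    ]
    return report, table


def make_scan(spec: PhantomSpec) -> PhantomScan:
    territories, heart = build_territories(spec)
    report, table = ground_truth_report(spec, territories, heart)
    ct = render_ct(spec, territories, heart)
    return PhantomScan(spec, ct, heart, territories, table, report)


# ---------------------------------------------------------------------------
# randomized datasets
# ---------------------------------------------------------------------------

def _sample_spec(rng: np.random.Generator, base: PhantomSpec,
                 lesion_free_rate: float, max_lesions: int,
                 hu_range: tuple[float, float], radius_range: tuple[float, float],
                 distractor_rate: float, scan_seed: int) -> PhantomSpec:
    semi = np.asarray(base.heart_semiaxes_mm) * rng.uniform(0.92, 1.08, size=3)
    center = base.center_mm + rng.uniform(-3.0, 3.0, size=3)

    lesions: list[Lesion] = []
    if rng.random() >= lesion_free_rate:
        n_les = int(rng.integers(1, max_lesions + 1))
        for _ in range(n_les):
            lesions.append(Lesion(
                vessel=int(rng.integers(1, 5)),
                t=float(rng.uniform(0.08, 0.92)),
                radius_mm=float(rng.uniform(*radius_range)),
                hu=float(rng.uniform(*hu_range)),
            ))

    distractors: list[Distractor] = []
    for kind in DISTRACTOR_KINDS:
        if rng.random() < distractor_rate:
            c0, r0, hu0 = DEFAULT_DISTRACTOR_GEOMETRY[kind]
            jitter = rng.uniform(-0.03, 0.03, size=3)
            distractors.append(Distractor(
                kind=kind,
                center=tuple(np.asarray(c0) + jitter),
                radius_mm=r0 * float(rng.uniform(0.9, 1.1)),
                hu=hu0 * float(rng.uniform(0.8, 1.2)),
            ))

    return replace(
        base,
        heart_center_mm=tuple(center),
        heart_semiaxes_mm=tuple(semi),
        lesions=tuple(lesions),
        distractors=tuple(distractors),
        seed=scan_seed,
    )


def simulate_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    lesion_free_rate: float = 1.0 / 3.0,
    max_lesions: int = 6,
    lesion_hu_range: tuple[float, float] = (160.0, 900.0),
    lesion_radius_range: tuple[float, float] = (1.4, 4.0),
    distractor_rate: float = 0.3,
) -> list[PhantomScan]:
    """Generate n randomized phantom scans, deterministic in `seed`.

    Roughly ``lesion_free_rate`` of scans carry no coronary calcium
    (default one third, matching a screening-style case mix); distractor
    calcifications appear independently per kind.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    master = np.random.SeedSequence(seed)
    scans = []
    for child in master.spawn(n):
        rng = np.random.default_rng(child)
        scan_seed = int(child.generate_state(1)[0] % (2 ** 31))
        for _ in range(20):  # re-draw if jitter lands a distractor in a territory
            spec = _sample_spec(rng, base, lesion_free_rate, max_lesions,
                                lesion_hu_range, lesion_radius_range,
                                distractor_rate, scan_seed)
            try:
                scans.append(make_scan(spec))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not sample a valid phantom spec")
    return scans


# ---------------------------------------------------------------------------
# annotation sources for training (what an expert / a fully-labelled
# contrast-derived scan would provide)
# ---------------------------------------------------------------------------

def sparse_annotations(scan: PhantomScan) -> np.ndarray:
    """Expert-style sparse labels: calcified voxels tagged with their vessel.

    Only coronary lesions are annotated (codes 1..4); distractor calcium
    and everything else stays 0 (unannotated).
    """
    ann = np.zeros(scan.spec.shape, dtype=np.int16)
    for les in scan.truth_report.lesions:
        if les.is_coronary:
            ann[les.voxels[:, 0], les.voxels[:, 1], les.voxels[:, 2]] = les.vessel
    return ann


def coronary_tube_labels(spec: PhantomSpec, tube_radius_mm: float = 2.5) -> np.ndarray:
    """Dense whole-course coronary labels (codes 1..4, 0 elsewhere).

    Emulates a fully labelled coronary tree transferred from a
    contrast-enhanced acquisition of the same anatomy.
    """
    territories, heart = build_territories(spec)
    inside = heart.voxels.astype(bool)
    hv = np.argwhere(inside)
    hv_mm = hv * np.asarray(spec.spacing)
    pts, tags = [], []
    for code in sorted(spec.vessels):
        dense = _curve_mm(spec, code)
        pts.append(dense)
        tags.append(np.full(len(dense), code))
    tree = cKDTree(np.concatenate(pts))
    tags = np.concatenate(tags)
    dist, idx = tree.query(hv_mm)
    lab = np.zeros(spec.shape, dtype=np.int16)
    keep = dist <= tube_radius_mm
    kept = hv[keep]
    lab[kept[:, 0], kept[:, 1], kept[:, 2]] = tags[idx[keep]]
    return lab
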
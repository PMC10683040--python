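"""Volume containers and NIfTI/DICOM I/O.

All in-memory arrays use the canonical axis order ``(slice, row, column)``
and ``spacing`` is stored axis-aligned as ``(dz, dy, dx)`` in millimetres.
Coordinates are 0-based and voxel-centred.  Every other module in the
package assumes this convention; the readers below are the only place
where on-disk axis conventions are translated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -2048.0
HU_MAX = 4096.0

#: Region codes used throughout the package.
LABEL_CODES = {
    0: "outside_heart",
    1: "LM",
    2: "LAD",
    3: "LCX",
    4: "RCA",
    5: "other",
}
VESSEL_CODES = (1, 2, 3, 4)


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values, axis order (slice, row, column).
    spacing : tuple of float
        (dz, dy, dx) voxel spacing in mm, aligned with the array axes.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm, (z, y, x).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="zyx", repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be rank-3 and nonempty, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU values out of range [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]")
        if self.axis_order != "zyx":
            raise ValueError("canonical axis order is (slice, row, column)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class HeartMask:
    """Binary heart-region mask sharing geometry with its CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be rank-3")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask values must be in {{0, 1}}, got {vals}")
        self.voxels = self.voxels.astype(np.uint8)
        if self.voxels.sum() < 1:
            raise ValueError("heart mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RegionLabelMap:
    """Per-voxel heart region codes.

    0 = outside heart, 1 = LM, 2 = LAD, 3 = LCX, 4 = RCA, 5 = other
    (non-coronary structures inside the heart: aorta, valves, chambers).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label map must be rank-3")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.array_equal(rounded, self.voxels):
                raise ValueError("label map voxels must be integral")
            self.voxels = rounded
        self.voxels = self.voxels.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.voxels), np.arange(6))
        if bad.size:
            raise ValueError(f"label codes outside {{0..5}}: {bad}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def check_inside(self, heart: HeartMask) -> bool:
        """True iff coronary/other codes lie inside the mask and 0 outside."""
        inside = heart.voxels.astype(bool)
        return bool(np.all((self.voxels >= 1) == inside))


Volume = CTVolume | HeartMask | RegionLabelMap


def check_alignment(a: Volume, b: Volume, tol: float = 1e-6) -> bool:
    """True iff two volumes share shape and spacing (within `tol` mm)."""
    if a.voxels.shape != b.voxels.shape:
        return False
    return all(abs(sa - sb) <= tol for sa, sb in zip(a.spacing, b.spacing))


def require_alignment(*vols: Volume) -> None:
    first = vols[0]
    for v in vols[1:]:
        if not check_alignment(first, v):
            raise ValueError(
                f"geometry mismatch: {first.voxels.shape}/{first.spacing} vs "
                f"{v.voxels.shape}/{v.spacing}"
            )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing, origin) -> np.ndarray:
    # On disk the array is stored (x, y, z); build an RAS-ish diagonal affine.
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume to NIfTI (.nii or .nii.gz).

    Label maps and masks are stored as integers; label maps additionally
    get a ``<stem>.labels.json`` sidecar with the code table.
    """
    path = Path(path)
    data = vol.voxels
    if isinstance(vol, (HeartMask, RegionLabelMap)):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine_from_geometry(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(reversed(vol.spacing)))
    nib.save(img, str(path))
    if isinstance(vol, RegionLabelMap):
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
        sidecar = sidecar.parent / (sidecar.name + ".labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in LABEL_CODES.items()}, indent=2))
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header has non-positive voxel spacing")
    origin = tuple(float(t) for t in img.affine[:3, 3][::-1])
    # stored (x, y, z) -> canonical (z, y, x)
    return np.transpose(data, (2, 1, 0)), tuple(float(z) for z in reversed(zooms)), origin


def read_volume(path: str | Path, format: str | None = None, kind: str = "ct") -> Volume:
    """Read a CT volume, mask, or label map.

    Parameters
    ----------
    path : str or Path
        A NIfTI file or a directory containing one DICOM series.
    format : {"nifti", "dicom_series"}, optional
        Inferred from the path when omitted.
    kind : {"ct", "mask", "labels"}
        Which container to return.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        voxels, spacing, origin = _read_nifti(path)
    elif format == "dicom_series":
        voxels, spacing, origin = _read_dicom_series(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if kind == "ct":
        return CTVolume(voxels.astype(np.float32), spacing, origin)
    if kind == "mask":
        return HeartMask(voxels.astype(np.uint8), spacing, origin)
    if kind == "labels":
        return RegionLabelMap(voxels, spacing, origin)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple, tuple]:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1 or None in uids:
        raise ValueError(f"directory does not contain exactly one DICOM series (UIDs: {uids})")

    for ds in datasets:
        for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
            if tag not in ds:
                raise ValueError(f"DICOM slice missing geometry tag {tag}")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("DICOM slice missing RescaleSlope/RescaleIntercept")

    # Sort by position projected on the slice normal (robust to renumbering).
    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    offsets = [float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal)) for ds in datasets]
    order = np.argsort(offsets, kind="stable")
    datasets = [datasets[i] for i in order]
    offsets = [offsets[i] for i in order]

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        hu = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(hu)
    voxels = np.stack(slices, axis=0)

    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    if len(datasets) > 1:
        deltas = np.diff(offsets)
        dz = float(np.mean(deltas))
        if dz <= 0 or np.ptp(deltas) > 1e-3:
            raise ValueError("inconsistent slice positions in series")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    pos0 = np.array(datasets[0].ImagePositionPatient, dtype=float)
    origin = (float(offsets[0]), float(pos0[1]), float(pos0[0]))
    return voxels, (dz, dy, dx), origin
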
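"""Training-supervision construction from sparse and automatic labels.

Supervision is deliberately partial: expert calcium annotations label only
calcified voxels with their vessel; an automatically generated mask labels
bright non-coronary structures (threshold > 10 HU inside the heart, then
morphological opening that removes thin tube-like structures, i.e. the
coronary arteries themselves); everything outside the heart is densely
labelled as class 0.  All remaining voxels carry the sentinel -1 and are
excluded from the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_volumes import CTVolume, HeartMask, require_alignment

OTHER_THRESHOLD_HU = 10.0
UNLABELLED = -1

#: radius-1 3D ball (6-connected octahedron) used for erosion/dilation
_BALL_R1 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SupervisionVolume:
    """Partial training labels plus the mask where loss is evaluated."""

    labels: np.ndarray  # int16, codes {0..5} or -1 (unlabelled)
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int16)
        bad = np.setdiff1d(np.unique(self.labels), np.arange(-1, 6))
        if bad.size:
            raise ValueError(f"supervision codes outside {{-1, 0..5}}: {bad}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def supervise(self) -> np.ndarray:
        return self.labels != UNLABELLED

    @property
    def n_supervised(self) -> int:
        return int(self.supervise.sum())


def sparse_from_annotations(
    annotations,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> SupervisionVolume:
    """Sparse vessel labels from expert calcium annotations.

    `annotations` is a voxel->vessel-code mapping, an iterable of
    ``((z, y, x), code)`` pairs, or a label volume with 0 = unannotated.
    Conflicting duplicate annotations are an error.
    """
    labels = np.full(shape, UNLABELLED, dtype=np.int16)
    if isinstance(annotations, np.ndarray):
        if annotations.shape != tuple(shape):
            raise ValueError("annotation volume shape mismatch")
        labels[annotations > 0] = annotations[annotations > 0]
        return SupervisionVolume(labels, spacing)
    items = annotations.items() if hasattr(annotations, "items") else annotations
    for voxel, code in items:
        z, y, x = voxel
        if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
            raise ValueError(f"annotation voxel {voxel} outside volume bounds {shape}")
        if labels[z, y, x] != UNLABELLED and labels[z, y, x] != code:
            raise ValueError(
                f"conflicting annotations at voxel {voxel}: "
                f"{labels[z, y, x]} vs {code}"
            )
        labels[z, y, x] = code
    return SupervisionVolume(labels, spacing)


def generate_other_labels(ct: CTVolume, heart: HeartMask, n_iter: int = 2) -> np.ndarray:
    """Automatic non-coronary ('other') labels.

    Bright structures inside the heart (strictly > 10 HU) are extracted,
    then opened with ``n_iter`` erosions followed by ``n_iter`` dilations
    (radius-1 3D ball).  The opening removes tube-like structures thinner
    than roughly 2*n_iter voxels — the coronary arteries — while retaining
    thick structures such as the blood pool, aortic wall, or annulus
    calcifications.  The result is a binary mask, always a subset of the
    heart region.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    require_alignment(ct, heart)
    bright = (ct.voxels > OTHER_THRESHOLD_HU) & heart.voxels.astype(bool)
    eroded = ndimage.binary_erosion(bright, structure=_BALL_R1, iterations=n_iter)
    # anti-extensive: the result is a subset of `bright`, hence of the heart
    return ndimage.binary_dilation(eroded, structure=_BALL_R1, iterations=n_iter)


def compose_supervision(
    sparse: SupervisionVolume,
    other: np.ndarray,
    heart: HeartMask,
    dense_coronary: np.ndarray | None = None,
) -> SupervisionVolume:
    """Priority-merge of all supervision sources into one volume.

    Sparse expert codes (and, at the same priority, optional dense
    coronary labels, e.g. from a fully labelled synthetic scan) win over
    the automatic other-mask, which wins over nothing; outside-heart
    voxels are densely labelled 0; the rest stays unlabelled.
    """
    if sparse.labels.shape != heart.voxels.shape or other.shape != heart.voxels.shape:
        raise ValueError("supervision source shape mismatch")
    labels = np.full(sparse.labels.shape, UNLABELLED, dtype=np.int16)
    inside = heart.voxels.astype(bool)

    if dense_coronary is not None:
        if dense_coronary.shape != labels.shape:
            raise ValueError("dense coronary label shape mismatch")
        sel = dense_coronary > 0
        labels[sel] = dense_coronary[sel]
    sel = sparse.labels != UNLABELLED
    labels[sel] = sparse.labels[sel]

    sel = other.astype(bool) & inside & (labels == UNLABELLED)
    labels[sel] = 5
    labels[~inside & (labels == UNLABELLED)] = 0
    return SupervisionVolume(labels, sparse.spacing)
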
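"""Pixel-to-voxel label transfer and train/test splitting.

The anatomical segmentation lives at pixel resolution; the spectra live
at voxel resolution.  A voting system brings the labels down: for each
voxel block the class proportions are computed over its *labeled* pixels
only, so partial annotation does not dilute the targets.  Voxels with no
labeled pixel, or with an exact tie for the majority class, stay
unlabeled (ties are additionally flagged).  The resulting proportions
serve directly as soft classification targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .io_formats import GridGeometry, LabelMask


class ShapeMismatchError(ValueError):
    """Mask shape inconsistent with the grid geometry."""


class ClassStarvationError(ValueError):
    """A class has too few labeled voxels to be split."""


@dataclass
class VoxelSoftLabels:
    """Voxel-level soft class targets obtained by voting.

    ``proportions`` is C x N (class fractions among labeled pixels per
    voxel; zero column where no pixel is labeled), ``hard_label`` holds
    the majority class id (0 = unlabeled or tied), ``tie`` flags exact
    majority ties, and ``labeled_pixels`` counts labeled pixels per voxel.
    """

    proportions: np.ndarray
    hard_label: np.ndarray
    tie: np.ndarray
    labeled_pixels: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.proportions.shape[0]

    @property
    def labeled_index(self) -> np.ndarray:
        return np.flatnonzero(self.hard_label > 0)


def vote_downsample(mask: LabelMask, geometry: GridGeometry) -> VoxelSoftLabels:
    """Vote pixel labels down to voxel-level soft targets."""
    if mask.labels.shape != geometry.image_shape:
        raise ShapeMismatchError(
            f"mask shape {mask.labels.shape} does not match image shape "
            f"{geometry.image_shape}"
        )
    C = mask.n_classes
    N = geometry.n_voxels
    counts = np.zeros((C, N), dtype=np.int64)
    f = geometry.upsample_factor
    blocks = mask.labels.reshape(geometry.rows, f, geometry.cols, f)
    for c in range(1, C + 1):
        counts[c - 1] = (blocks == c).sum(axis=(1, 3)).ravel()

    labeled = counts.sum(axis=0)
    proportions = np.zeros_like(counts, dtype=float)
    np.divide(counts, labeled, where=labeled > 0, out=proportions)

    top = counts.max(axis=0)
    tie = (top > 0) & ((counts == top).sum(axis=0) > 1)
    hard = np.where((labeled > 0) & ~tie, counts.argmax(axis=0) + 1, 0)
    return VoxelSoftLabels(
        proportions=proportions,
        hard_label=hard.astype(np.int64),
        tie=tie,
        labeled_pixels=labeled,
    )


def split_train_test(
    labels: VoxelSoftLabels, fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of the labeled voxels into train/test index arrays.

    The split covers labeled voxels only (train and test are disjoint and
    together exhaust them), is stratified by hard label, and is a
    deterministic function of the seed.
    """
    idx = labels.labeled_index
    strata = labels.hard_label[idx]
    classes, counts = np.unique(strata, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        short = classes[counts.argmin()] if len(classes) else None
        raise ClassStarvationError(
            f"need >=2 labeled voxels in every class for a stratified split "
            f"(class {short} has {counts.min() if len(classes) else 0})"
        )
    train, test = train_test_split(
        idx, train_size=fraction, stratify=strata, random_state=seed
    )
    return np.sort(train), np.sort(test)
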
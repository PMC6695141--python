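"""From mixing proportions to pixel-resolution nosologic maps.

Factor order out of a factorisation is arbitrary, so sources are first
matched one-to-one to tissue classes by maximising each source's mean
abundance over the voxels labeled with each class.  The class-ordered
proportion fields are then bilinearly interpolated from the voxel grid
up to the anatomical-image resolution (voxel values anchored at block
centres, edge-replicated beyond the outer centres), renormalised per
pixel, and arg-maxed into a colour-coded class map (red = tumour,
blue = normal, yellow = third region).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .convex_nmf import MixingMatrix
from .io_formats import GridGeometry
from .label_transfer import VoxelSoftLabels

CLASS_COLOURS = {0: (0, 0, 0), 1: (255, 0, 0), 2: (0, 0, 255), 3: (255, 255, 0)}


class SourceAssignmentError(ValueError):
    """Source count does not match the number of labeled classes."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance)."""


@dataclass
class SegmentationMap:
    """Class-assigned segmentation at voxel and pixel resolution."""

    voxel_assignment: np.ndarray    # N class ids
    pixel_map: np.ndarray           # H x W class ids (argmax of proportions)
    pixel_proportions: np.ndarray   # C x H x W, per-pixel simplex
    class_ids: np.ndarray           # class id of each proportion channel

    def class_mask(self, class_id: int = 1) -> np.ndarray:
        """Binary pixel mask of one class (default tumour)."""
        return (self.pixel_map == class_id).astype(np.int64)

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.pixel_map.shape, 3), dtype=np.uint8)
        for cid in np.unique(self.pixel_map):
            rgb[self.pixel_map == cid] = CLASS_COLOURS.get(int(cid), (128, 128, 128))
        return rgb


def assign_sources_to_classes(
    mixing: MixingMatrix | np.ndarray, labels: VoxelSoftLabels
) -> np.ndarray:
    """Match each source to a tissue class, returning class ids per source.

    Solved exactly by enumerating permutations (k is 2 or 3 in practice):
    the chosen matching maximises the summed mean mixing proportion of
    each source over the voxels hard-labeled with its class.
    """
    P = mixing.proportions if isinstance(mixing, MixingMatrix) else np.asarray(mixing)
    k = P.shape[0]
    class_ids = np.unique(labels.hard_label[labels.hard_label > 0])
    if len(class_ids) != k:
        raise SourceAssignmentError(
            f"{k} sources but {len(class_ids)} labeled classes; set the number "
            f"of sources to the number of segmented classes"
        )
    score = np.stack(
        [P[:, labels.hard_label == cid].mean(axis=1) for cid in class_ids], axis=1
    )  # k sources x k classes
    best = max(permutations(range(k)), key=lambda pi: sum(score[s, pi[s]] for s in range(k)))
    return class_ids[list(best)]


def interpolate_map(
    mixing: MixingMatrix | np.ndarray,
    geometry: GridGeometry,
    source_classes: np.ndarray | None = None,
) -> SegmentationMap:
    """Bilinearly upsample per-voxel proportions to a pixel-level map.

    Voxel proportions are anchored at the centres of their pixel blocks,
    interpolated to every pixel centre with edge replication, clipped to
    [0, 1] and renormalised per pixel before the per-pixel argmax.
    """
    P = mixing.proportions if isinstance(mixing, MixingMatrix) else np.asarray(mixing)
    k = P.shape[0]
    if source_classes is None:
        source_classes = np.arange(1, k + 1)
    source_classes = np.asarray(source_classes)

    R, C, f = geometry.rows, geometry.cols, geometry.upsample_factor
    H, W = geometry.image_shape
    r_centers = (np.arange(R) + 0.5) * f - 0.5
    c_centers = (np.arange(C) + 0.5) * f - 0.5
    ri = np.clip(np.arange(H), r_centers[0], r_centers[-1])
    ci = np.clip(np.arange(W), c_centers[0], c_centers[-1])
    pts = np.stack(np.meshgrid(ri, ci, indexing="ij"), axis=-1)

    fields = np.empty((k, H, W))
    for s in range(k):
        interp = RegularGridInterpolator(
            (r_centers, c_centers), P[s].reshape(R, C), method="linear"
        )
        fields[s] = interp(pts)
    fields = np.clip(fields, 0.0, 1.0)
    totals = fields.sum(axis=0)
    fields = np.where(totals > 0, fields / np.where(totals > 0, totals, 1.0), 1.0 / k)

    # order channels by class id so channel i holds class class_ids[i]
    order = np.argsort(source_classes)
    fields = fields[order]
    class_ids = source_classes[order]
    pixel_map = class_ids[fields.argmax(axis=0)]
    voxel_assignment = source_classes[P.argmax(axis=0)]
    return SegmentationMap(
        voxel_assignment=voxel_assignment,
        pixel_map=pixel_map,
        pixel_proportions=fields,
        class_ids=class_ids,
    )


def source_correlation(s1, s2) -> float:
    """Pearson correlation between two source spectra."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("spectra must have equal length")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise UndefinedCorrelationError("zero-variance spectrum")
    return float(np.corrcoef(s1, s2)[0, 1])
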
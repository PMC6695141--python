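"""Segmentation evaluation against a gold-standard tumour mask.

Covers the full comparison suite: confusion-based rates (sensitivity
TP/(TP+FN), specificity TN/(TN+FP)), the Sorensen-Dice overlap
2TP/(2TP+FP+FN), the Euclidean distance between binary map encodings
(whose square equals the mismatch count), the companion shape-similarity
percentage, the Hausdorff distance between region boundaries, and a
Kruskal-Wallis rank test across methods.  Tumour is the positive class
throughout; all metrics are computed over the pixel footprint of the
MRSI grid, where the maps exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import kruskal as _scipy_kruskal


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty for these masks."""


class EmptyMaskError(ValueError):
    """Boundary extraction requires a nonempty region."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _binary(mask) -> np.ndarray:
    return (np.asarray(mask) != 0)


def confusion_counts(pred, gold, footprint=None) -> ConfusionCounts:
    """Pixel confusion counts; optionally restricted to a footprint mask."""
    pred, gold = _binary(pred), _binary(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gold.shape}")
    if footprint is not None:
        keep = _binary(footprint)
        if keep.shape != pred.shape:
            raise ValueError("footprint shape mismatch")
        pred, gold = pred[keep], gold[keep]
    return ConfusionCounts(
        tp=int(np.sum(pred & gold)),
        fp=int(np.sum(pred & ~gold)),
        tn=int(np.sum(~pred & ~gold)),
        fn=int(np.sum(~pred & gold)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive pixels")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative pixels")
    return c.tn / (c.tn + c.fp)


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return 2 * c.tp / denom


def euclidean_distance(E, G) -> float:
    """Euclidean distance between 0/1 map encodings; zero iff identical."""
    E, G = _binary(E), _binary(G)
    if E.shape != G.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.sum((E.astype(float) - G.astype(float)) ** 2)))


def shape_similarity(E, G) -> float:
    """Percentage of pixels whose values match between the two maps."""
    E, G = _binary(E), _binary(G)
    if E.shape != G.shape:
        raise ValueError("shape mismatch")
    return 100.0 * float(np.mean(E == G))


def boundary(mask) -> np.ndarray:
    """Region pixels with a 4-neighbour outside the region (or on the border).

    Returns an (n, 2) array of (row, col) coordinates.
    """
    m = _binary(mask)
    if not m.any():
        raise EmptyMaskError("cannot extract the boundary of an empty mask")
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def hausdorff(b_e: np.ndarray, b_g: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two boundary point sets."""
    b_e, b_g = np.atleast_2d(b_e), np.atleast_2d(b_g)
    if b_e.size == 0 or b_g.size == 0:
        raise EmptyMaskError("Hausdorff distance requires nonempty point sets")
    return max(
        directed_hausdorff(b_e, b_g)[0], directed_hausdorff(b_g, b_e)[0]
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across >= 2 groups.

    With every observation identical the tie correction degenerates; the
    test is then reported as (H=0, p=1) with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; Kruskal-Wallis H undefined, reporting 0")
        return 0.0, 1.0
    stat, p = _scipy_kruskal(*groups)
    return float(stat), float(p)


def evaluate_masks(pred, gold, footprint=None) -> dict[str, float]:
    """All six comparison metrics between a predicted and a gold tumour mask."""
    c = confusion_counts(pred, gold, footprint=footprint)
    return {
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "dice": dice(c),
        "euclidean_distance": euclidean_distance(pred, gold),
        "shape_similarity_pct": shape_similarity(pred, gold),
        "hausdorff": hausdorff(boundary(pred), boundary(gold)),
    }
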
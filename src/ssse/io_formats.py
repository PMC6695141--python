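"""Data containers and file formats.

The package moves four kinds of data around: MRSI grids (one spectrum per
voxel), anatomical images at a higher in-plane resolution, integer label
masks over those images, and evaluation reports.  Grids, masks and images
all have a delimited-text dialect whose write/read round trip is exact;
images and masks can additionally be exchanged as grayscale PNG (with
documented 8/16-bit quantisation).  Reports are schema-versioned JSON.

The voxel-to-pixel convention is declared once, in :class:`GridGeometry`,
and reused everywhere: voxel ``(r, c)`` of an ``R x C`` grid covers the
half-open pixel block ``[r*f, (r+1)*f) x [c*f, (c+1)*f)`` of the
``R*f x C*f`` image, 0-based and row-major.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import imageio.v3 as iio
import numpy as np

REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent file content."""


class LabelRangeError(ValueError):
    """A mask contains a label id above the declared number of classes."""


@dataclass(frozen=True)
class GridGeometry:
    """Mapping between the MRSI voxel grid and the anatomical pixel raster.

    Parameters
    ----------
    rows, cols : int
        MRSI grid shape.
    upsample_factor : int
        Pixels per voxel side; the image is ``rows*f x cols*f``.
    """

    rows: int
    cols: int
    upsample_factor: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.upsample_factor < 1:
            raise ValueError("rows, cols and upsample_factor must be >= 1")

    @property
    def n_voxels(self) -> int:
        return self.rows * self.cols

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.rows * self.upsample_factor, self.cols * self.upsample_factor)

    def voxel_block(self, r: int, c: int) -> tuple[slice, slice]:
        """Half-open pixel slices covered by voxel ``(r, c)``."""
        f = self.upsample_factor
        return slice(r * f, (r + 1) * f), slice(c * f, (c + 1) * f)


@dataclass
class MRSIGrid:
    """An R x C grid of voxel spectra.

    ``data`` holds one spectrum per column (``D x N``, row-major voxel
    order, mixed-sign values allowed); ``ppm_axis`` is the strictly
    decreasing chemical-shift axis shared by all voxels.
    """

    data: np.ndarray
    ppm_axis: np.ndarray
    rows: int
    cols: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("grid data must be a 2-D (D x N) array")
        if self.data.shape[1] != self.rows * self.cols:
            raise FormatError(
                f"expected {self.rows * self.cols} voxel spectra, "
                f"got {self.data.shape[1]}"
            )
        if self.ppm_axis.shape != (self.data.shape[0],):
            raise FormatError("ppm axis length must match number of spectral points")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise FormatError("ppm axis must be strictly decreasing")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("grid contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class AnatomicalImage:
    """Grayscale anatomical image co-registered with an MRSI grid."""

    pixels: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.geometry.image_shape:
            raise FormatError(
                f"image shape {self.pixels.shape} does not match geometry "
                f"{self.geometry.image_shape}"
            )
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise FormatError("image pixels must be finite and nonnegative")


@dataclass
class LabelMask:
    """Pixel-level class labels: 0 = unlabeled, 1 = tumour, 2.. = other."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise FormatError("mask labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.min() < 0 or self.labels.max() > self.n_classes:
            raise LabelRangeError(
                f"mask labels must lie in 0..{self.n_classes}, "
                f"found {int(self.labels.max())}"
            )


@dataclass
class EvaluationReport:
    """Per-method, per-case segmentation metrics plus group statistics.

    ``records`` is a list of dicts with keys ``method``, ``case`` and the
    six metrics (sensitivity, specificity, dice, euclidean_distance,
    shape_similarity_pct, hausdorff); ``summaries`` maps method name to
    per-metric (mean, sd); ``kruskal_wallis`` maps metric name to an
    (H, p-value) pair across methods.
    """

    records: list[dict[str, Any]] = field(default_factory=list)
    summaries: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    kruskal_wallis: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# delimited-text grid dialect


def write_grid(grid: MRSIGrid, path) -> None:
    """Write a grid in the delimited-text dialect (full float precision)."""
    with open(path, "w") as fh:
        fh.write(
            f"# mrsi-grid rows={grid.rows} cols={grid.cols} "
            f"points={grid.n_points} "
            f"ppm_high={float(grid.ppm_axis[0])!r} "
            f"ppm_low={float(grid.ppm_axis[-1])!r}\n"
        )
        for j in range(grid.n_voxels):
            fh.write("\t".join(repr(float(v)) for v in grid.data[:, j]) + "\n")


def read_grid(path) -> MRSIGrid:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# mrsi-grid"):
            raise FormatError(f"{path}: missing mrsi-grid header")
        meta = dict(tok.split("=", 1) for tok in header.split()[2:])
        try:
            rows, cols, n_points = (
                int(meta["rows"]), int(meta["cols"]), int(meta["points"]),
            )
            ppm_high, ppm_low = float(meta["ppm_high"]), float(meta["ppm_low"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: bad header: {header.strip()}") from exc
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) != rows * cols:
        raise FormatError(
            f"{path}: header declares {rows * cols} voxels, found {len(lines)} lines"
        )
    data = np.empty((n_points, rows * cols))
    for j, ln in enumerate(lines):
        vals = ln.split("\t")
        if len(vals) != n_points:
            raise FormatError(
                f"{path}: voxel line {j} has {len(vals)} values, expected {n_points}"
            )
        data[:, j] = [float(v) for v in vals]
    ppm = np.linspace(ppm_high, ppm_low, n_points)
    return MRSIGrid(data=data, ppm_axis=ppm, rows=rows, cols=cols)


# ---------------------------------------------------------------------------
# masks and images


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask: ``.png`` as 8-bit grayscale, else delimited text."""
    path = str(path)
    if path.endswith(".png"):
        if mask.n_classes > 255:
            raise FormatError("PNG mask export supports at most 255 classes")
        iio.imwrite(path, mask.labels.astype(np.uint8))
    else:
        with open(path, "w") as fh:
            fh.write(f"# label-mask n_classes={mask.n_classes}\n")
            np.savetxt(fh, mask.labels, fmt="%d", delimiter="\t")


def read_mask(path, n_classes: int | None = None) -> LabelMask:
    path = str(path)
    if path.endswith(".png"):
        labels = np.asarray(iio.imread(path)).astype(np.int64)
        if labels.ndim != 2:
            raise FormatError(f"{path}: mask PNG must be single-channel grayscale")
        if n_classes is None:
            n_classes = int(labels.max()) if labels.size else 1
    else:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# label-mask"):
                raise FormatError(f"{path}: missing label-mask header")
            declared = int(header.split("n_classes=")[1])
            labels = np.loadtxt(fh, dtype=np.int64, delimiter="\t", ndmin=2)
        if n_classes is None:
            n_classes = declared
    return LabelMask(labels=labels, n_classes=n_classes)


def write_image(image: AnatomicalImage, path, bit_depth: int = 16) -> None:
    """Write an image: ``.png`` quantised to 8/16-bit, else exact delimited text.

    PNG export linearly rescales ``[0, max]`` onto the integer range, so it
    is lossy; the delimited dialect round-trips exactly.
    """
    path = str(path)
    if path.endswith(".png"):
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        top = 2**bit_depth - 1
        peak = float(image.pixels.max())
        scaled = image.pixels / peak * top if peak > 0 else image.pixels
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        iio.imwrite(path, np.round(scaled).astype(dtype))
    else:
        with open(path, "w") as fh:
            fh.write(
                f"# anatomical-image rows={image.geometry.rows} "
                f"cols={image.geometry.cols} "
                f"factor={image.geometry.upsample_factor}\n"
            )
            for row in image.pixels:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_image(path, geometry: GridGeometry | None = None) -> AnatomicalImage:
    path = str(path)
    if path.endswith(".png"):
        pixels = np.asarray(iio.imread(path)).astype(float)
        if geometry is None:
            raise ValueError("geometry is required when reading PNG images")
    else:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# anatomical-image"):
                raise FormatError(f"{path}: missing anatomical-image header")
            meta = dict(tok.split("=", 1) for tok in header.split()[2:])
            geometry = GridGeometry(
                rows=int(meta["rows"]),
                cols=int(meta["cols"]),
                upsample_factor=int(meta["factor"]),
            )
            pixels = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if pixels.shape != geometry.image_shape:
        raise FormatError(
            f"{path}: image shape {pixels.shape} does not match geometry"
        )
    return AnatomicalImage(pixels=pixels, geometry=geometry)


# ---------------------------------------------------------------------------
# reports


def write_report(report: EvaluationReport, path) -> None:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "records": report.records,
        "summaries": report.summaries,
        "kruskal_wallis": report.kruskal_wallis,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")


def read_report(path) -> EvaluationReport:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported report schema version")
    return EvaluationReport(
        records=payload["records"],
        summaries={
            m: {k: tuple(v) for k, v in s.items()}
            for m, s in payload["summaries"].items()
        },
        kruskal_wallis={k: tuple(v) for k, v in payload["kruskal_wallis"].items()},
    )
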
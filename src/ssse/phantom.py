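"""Synthetic MRSI/MRI phantoms with known ground truth.

Real preclinical glioblastoma MRSI acquisitions are not publicly
deposited, so development and validation run on phantoms that emulate the
structure of such data: a small voxel grid (default 10x10) of long-echo
proton spectra (default 692 points on a 4.5..0 ppm axis), an elliptical
tumour whose rim mixes smoothly into normal parenchyma, a co-registered
anatomical image at higher in-plane resolution, a partial label mask that
leaves the uncertain rim unlabeled, and a pixel-level gold-standard tumour
mask.

Each tissue class is a sum of Gaussian metabolite peaks at the canonical
chemical shifts: choline 3.21 ppm, creatine 3.03 ppm, N-acetyl aspartate
2.02 ppm, and lactate/mobile lipids around 1.3 ppm.  Tumour spectra show
high Cho and Lac/ML with depressed NAA; normal parenchyma the reverse.
An optional third pattern (for multi-region experiments, or as an
unlabeled confounder) adds a strong out-of-class resonance at 3.8 ppm on
an otherwise normal-looking profile.

Voxel spectra are ``sources @ abundances`` plus i.i.d. Gaussian noise
scaled so that (strongest peak amplitude) / (noise sd) equals ``snr``.
Abundances are convex weights driven by a logistic function of the signed
distance to the tumour ellipse, so partial-volume voxels at the rim are
genuinely mixed -- the situation a source-extraction method must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import AnatomicalImage, GridGeometry, LabelMask, MRSIGrid

# (ppm_center, amplitude, Gaussian sigma in ppm) per class
TUMOUR_PEAKS = ((3.21, 1.0, 0.035), (3.03, 0.45, 0.035), (2.02, 0.2, 0.045), (1.30, 3.0, 0.09))
NORMAL_PEAKS = ((3.21, 0.55, 0.035), (3.03, 0.85, 0.035), (2.02, 1.4, 0.045), (1.30, 0.15, 0.09))
THIRD_PEAKS = ((3.80, 6.0, 0.05), (3.21, 0.5, 0.035), (3.03, 0.8, 0.035), (2.02, 1.3, 0.045))


class PeakOutOfRangeError(ValueError):
    """A peak centre lies outside the spectral ppm range."""


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in continuous voxel coordinates (voxel (r,c) spans [r,r+1)x[c,c+1))."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rim_softness: float = 0.35

    def signed_distance(self, r, c) -> np.ndarray:
        """Approximate signed distance to the boundary (negative inside)."""
        a, b = self.semi_axes
        rad = np.sqrt(((r - self.center[0]) / a) ** 2 + ((c - self.center[1]) / b) ** 2)
        return (rad - 1.0) * min(a, b)

    def membership(self, r, c) -> np.ndarray:
        """Logistic soft membership: 1 deep inside, 0 far outside, 0.5 on rim."""
        return 1.0 / (1.0 + np.exp(self.signed_distance(r, c) / self.rim_softness))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``n_classes`` counts the labeled tissue classes (2 or 3).  A third
    spectral pattern can instead be injected *without* labels by setting
    ``confounder_geometry`` while keeping ``n_classes=2``; this emulates
    an unexpected region (ventricle, artefact) the annotator did not mark.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    n_points: int = 692
    ppm_range: tuple[float, float] = (4.5, 0.0)
    upsample_factor: int = 10
    n_classes: int = 2
    peak_table: tuple[tuple[tuple[float, float, float], ...], ...] | None = None
    tumour_geometry: Ellipse = field(
        default_factory=lambda: Ellipse((4.8, 5.3), (2.6, 2.0))
    )
    third_geometry: Ellipse | None = None
    confounder_geometry: Ellipse | None = None
    snr: float = 10.0
    label_margin: float | None = None  # rim half-width left unlabeled; default 2*softness
    unlabeled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.n_points < 2:
            raise PhantomSpecError("grid must be at least 1x1 with >=2 points")
        if self.upsample_factor < 1:
            raise PhantomSpecError("upsample_factor must be a positive integer")
        if not self.ppm_range[0] > self.ppm_range[1]:
            raise PhantomSpecError("ppm_range must be (high, low) with high > low")
        if self.n_classes not in (2, 3):
            raise PhantomSpecError("n_classes must be 2 or 3")
        if not self.snr > 0:
            raise PhantomSpecError("snr must be positive")
        if self.n_classes == 3 and self.third_geometry is None:
            object.__setattr__(
                self, "third_geometry", Ellipse((7.8, 2.2), (1.4, 1.3), 0.3)
            )
        if self.n_classes == 3 and self.confounder_geometry is not None:
            raise PhantomSpecError("use either a labeled third class or a confounder")
        if self.peak_table is None:
            table = [TUMOUR_PEAKS, NORMAL_PEAKS]
            if self.n_regions == 3:
                table.append(THIRD_PEAKS)
            object.__setattr__(self, "peak_table", tuple(table))
        if len(self.peak_table) != self.n_regions:
            raise PhantomSpecError(
                f"peak_table must have {self.n_regions} entries, got {len(self.peak_table)}"
            )
        for peaks in self.peak_table:
            for center, amplitude, width in peaks:
                if amplitude < 0 or width <= 0:
                    raise PhantomSpecError("peak amplitudes >= 0 and widths > 0 required")
        self._check_inside(self.tumour_geometry)
        for geom in (self.third_geometry, self.confounder_geometry):
            if geom is not None:
                self._check_inside(geom)

    def _check_inside(self, e: Ellipse) -> None:
        (r0, c0), (a, b) = e.center, e.semi_axes
        if not (0 <= r0 - a and r0 + a <= self.grid_rows and 0 <= c0 - b and c0 + b <= self.grid_cols):
            raise PhantomSpecError("ellipse must lie within the voxel grid")

    @property
    def n_regions(self) -> int:
        """Number of distinct spectral patterns (classes plus any confounder)."""
        return self.n_classes + (1 if self.confounder_geometry is not None else 0)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols, self.upsample_factor)

    @property
    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)


@dataclass
class PhantomTruth:
    """Ground truth behind a phantom: noiseless sources, mixing, tumour mask."""

    true_sources: np.ndarray       # D x k
    true_abundances: np.ndarray    # k x N, columns are convex weights
    true_pixel_mask: np.ndarray    # H x W binary tumour indicator

    def __post_init__(self) -> None:
        col_sums = self.true_abundances.sum(axis=0)
        if np.any(self.true_abundances < -1e-12) or np.any(np.abs(col_sums - 1) > 1e-12):
            raise ValueError("abundance columns must be convex weights")


def make_source_library(spec: PhantomSpec) -> np.ndarray:
    """Render each region's peak list into a nonnegative D x k source matrix."""
    ppm = spec.ppm_axis
    sources = np.zeros((spec.n_points, spec.n_regions))
    for k, peaks in enumerate(spec.peak_table):
        for center, amplitude, width in peaks:
            if not (spec.ppm_range[1] <= center <= spec.ppm_range[0]):
                raise PeakOutOfRangeError(
                    f"peak at {center} ppm outside range {spec.ppm_range}"
                )
            sources[:, k] += amplitude * np.exp(-0.5 * ((ppm - center) / width) ** 2)
    return sources


def _region_abundances(spec: PhantomSpec, r, c) -> np.ndarray:
    """Convex per-region weights at continuous voxel coordinates (r, c)."""
    tum = spec.tumour_geometry.membership(r, c)
    third_geom = spec.third_geometry or spec.confounder_geometry
    weights = [tum]
    if third_geom is not None:
        third = third_geom.membership(r, c) * (1.0 - tum)
        normal = 1.0 - tum - third
        weights = [tum, normal, third]
    else:
        weights = [tum, 1.0 - tum]
    return np.stack(weights)


def make_phantom(
    spec: PhantomSpec,
) -> tuple[MRSIGrid, AnatomicalImage, LabelMask, np.ndarray, PhantomTruth]:
    """Generate one phantom case.

    Returns the MRSI grid, the anatomical image, the partial label mask,
    the gold-standard pixel tumour mask, and the generating truth.  Output
    is a deterministic function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    geometry = spec.geometry
    sources = make_source_library(spec)

    # voxel-centre abundances
    rr, cc = np.meshgrid(
        np.arange(spec.grid_rows) + 0.5, np.arange(spec.grid_cols) + 0.5, indexing="ij"
    )
    abundances = _region_abundances(spec, rr.ravel(), cc.ravel())  # k x N

    clean = sources @ abundances
    sigma = 0.0 if np.isinf(spec.snr) else float(sources.max()) / spec.snr
    data = clean + rng.normal(0.0, sigma, clean.shape) if sigma > 0 else clean.copy()
    grid = MRSIGrid(data=data, ppm_axis=spec.ppm_axis, rows=spec.grid_rows, cols=spec.grid_cols)

    # pixel-level fields
    H, W = geometry.image_shape
    f = spec.upsample_factor
    pr, pc = np.meshgrid((np.arange(H) + 0.5) / f, (np.arange(W) + 0.5) / f, indexing="ij")
    d_tum = spec.tumour_geometry.signed_distance(pr, pc)
    mu_tum = spec.tumour_geometry.membership(pr, pc)
    gold_mask = (d_tum < 0).astype(np.int64)

    extra_geom = spec.third_geometry or spec.confounder_geometry
    mu_extra = extra_geom.membership(pr, pc) if extra_geom is not None else np.zeros((H, W))
    intensity = 0.35 + 0.45 * mu_tum + 0.2 * mu_extra + rng.normal(0.0, 0.02, (H, W))
    image = AnatomicalImage(pixels=np.clip(intensity, 0.0, None), geometry=geometry)

    margin = spec.label_margin
    if margin is None:
        margin = 2.0 * spec.tumour_geometry.rim_softness
    labels = np.zeros((H, W), dtype=np.int64)
    labels[d_tum <= -margin] = 1
    labels[d_tum >= margin] = 2
    if extra_geom is not None:
        d_extra = extra_geom.signed_distance(pr, pc)
        if spec.n_classes == 3:
            labels[(d_extra <= -margin) & (labels != 1)] = 3
            labels[(np.abs(d_extra) < margin) & (labels != 1)] = 0
        else:  # confounder: region and its rim stay unlabeled
            labels[(d_extra < margin) & (labels != 1)] = 0
    if spec.unlabeled_fraction > 0:
        drop = rng.random((H, W)) < spec.unlabeled_fraction
        labels[drop] = 0
    mask = LabelMask(labels=labels, n_classes=spec.n_classes)

    truth = PhantomTruth(
        true_sources=sources, true_abundances=abundances, true_pixel_mask=gold_mask
    )
    return grid, image, mask, gold_mask, truth


def confounder_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A default two-class phantom carrying an unlabeled third spectral region."""
    base = PhantomSpec(
        confounder_geometry=Ellipse((7.8, 2.2), (1.4, 1.3), 0.3), seed=seed
    )
    return replace(base, **overrides) if overrides else base
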
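"""End-to-end orchestration of segmentation-guided source extraction.

Two modes share all downstream machinery and differ only in what is
factorised:

* ``ssse`` -- the segmentation-guided method: pixel labels are voted
  down to voxel-level soft targets, an MLP posterior model is trained on
  75% of the labeled voxels, the Fisher-Information metric it induces is
  embedded by classical MDS, and Convex-NMF runs on the embedded
  coordinates of *all* voxels (labeled and unlabeled).
* ``unsupervised`` -- Convex-NMF directly on the voxel spectra, the
  no-prior-knowledge baseline.

Either way the convexity weights are carried back to the original
spectra for interpretable spectral-domain sources, and the mixing
proportions are bilinearly interpolated to a pixel-resolution nosologic
map.  Each run handles a single case: the method deliberately models
one subject at a time and never pools spectra across subjects.

Every run is a deterministic function of (config, seed): a master seed
fans out to per-stage seeds (split, MLP init, factorisation init)
through independent seed sequences.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml

from .convex_nmf import (MixingMatrix, SourceSet, convex_nmf,
                         mixing_proportions, spectral_sources)
from .evaluation import evaluate_masks, kruskal_wallis
from .fisher_embedding import FisherEmbedding
from .io_formats import EvaluationReport, GridGeometry, LabelMask, MRSIGrid
from .label_transfer import split_train_test, vote_downsample
from .mapping import SegmentationMap, assign_sources_to_classes, interpolate_map
from .mlp import SoftLabelMLP
from .phantom import PhantomSpec, make_phantom

METRIC_NAMES = (
    "sensitivity", "specificity", "dice",
    "euclidean_distance", "shape_similarity_pct", "hausdorff",
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Tunable parameters of a run, loadable from a YAML config."""

    mode: str = "ssse"                 # ssse | unsupervised | both
    k: int = 2                         # number of sources = segmented classes
    train_fraction: float = 0.75
    mlp: dict[str, Any] = field(default_factory=dict)   # SoftLabelMLP overrides
    fi_segments: int = 10
    variance_keep: float = 0.99
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    normalize_spectra: bool = True     # L2-normalise voxel spectra before the MLP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ssse", "unsupervised", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    """Everything one pipeline run produces."""

    sources: SourceSet
    mixing: MixingMatrix
    segmentation: SegmentationMap
    log: dict[str, Any]


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _normalized(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.where(norms > 0, norms, 1.0)


def _geometry_for(grid: MRSIGrid, mask: LabelMask) -> GridGeometry:
    h = mask.labels.shape[0]
    if h % grid.rows:
        raise ValueError("mask height is not a multiple of the grid rows")
    return GridGeometry(grid.rows, grid.cols, h // grid.rows)


def run_ssse(grid: MRSIGrid, mask: LabelMask, config: PipelineConfig) -> RunResult:
    """Run the segmentation-guided pipeline on one case."""
    s_split, s_mlp, s_nmf = _stage_seeds(config.seed)
    log: dict[str, Any] = {"mode": "ssse", "seed": config.seed,
                           "stage_seeds": [s_split, s_mlp, s_nmf]}
    try:
        geometry = _geometry_for(grid, mask)
        votes = vote_downsample(mask, geometry)
        train, test = split_train_test(votes, config.train_fraction, seed=s_split)
        log["n_labeled"] = int(len(votes.labeled_index))
        log["n_train"], log["n_test"] = int(len(train)), int(len(test))
    except Exception as exc:
        raise PipelineStageError("label_transfer", exc) from exc

    X = grid.data.T
    if config.normalize_spectra:
        X = _normalized(X)
    targets = votes.proportions.T

    try:
        mlp = SoftLabelMLP(random_state=s_mlp, **config.mlp)
        mlp.fit(X[train], targets[train], X_val=X[test], y_val=targets[test])
        log["mlp_epochs"] = mlp.n_iter_
        log["mlp_train_loss"] = float(mlp.final_loss_)
        log["mlp_test_loss"] = float(mlp.validation_loss_)
        log["mlp_test_accuracy"] = float(mlp.validation_accuracy_)
    except Exception as exc:
        raise PipelineStageError("train_mlp", exc) from exc

    try:
        emb = FisherEmbedding(mlp, n_segments=config.fi_segments,
                              variance_keep=config.variance_keep)
        coords = emb.fit_transform(X)
        log["fi_segments"] = config.fi_segments
        log["mds_components"] = int(emb.n_components_)
        log["mds_negative_mass"] = float(emb.negative_mass_)
    except Exception as exc:
        raise PipelineStageError("fisher_embedding", exc) from exc

    return _factorise_and_map(
        coords.T, grid, votes, geometry, config, s_nmf, log
    )


def run_unsupervised(
    grid: MRSIGrid, config: PipelineConfig, mask: LabelMask | None = None,
    geometry: GridGeometry | None = None,
) -> RunResult:
    """Run the unsupervised Convex-NMF baseline on one case.

    The mask is not used by the factorisation; if given, it only names
    which source is which tissue class.
    """
    *_, s_nmf = _stage_seeds(config.seed)
    log: dict[str, Any] = {"mode": "unsupervised", "seed": config.seed}
    votes = None
    if mask is not None:
        geometry = _geometry_for(grid, mask)
        votes = vote_downsample(mask, geometry)
    elif geometry is None:
        raise ValueError("geometry is required when no mask is given")
    return _factorise_and_map(grid.data, grid, votes, geometry, config, s_nmf, log)


def _factorise_and_map(Y, grid, votes, geometry, config, seed, log) -> RunResult:
    try:
        factors = convex_nmf(
            Y, config.k, max_iter=config.nmf_max_iter, tol=config.nmf_tol, seed=seed
        )
        log["k"] = config.k
        log["nmf_iterations"] = int(len(factors.objective_trace) - 1)
        log["nmf_objective"] = float(factors.objective_trace[-1])
        sources = spectral_sources(grid.data, factors)
        mixing = mixing_proportions(factors)
    except Exception as exc:
        raise PipelineStageError("convex_nmf", exc) from exc

    try:
        if votes is not None:
            source_classes = assign_sources_to_classes(mixing, votes)
        else:
            source_classes = np.arange(1, config.k + 1)
        log["source_classes"] = [int(c) for c in source_classes]
        segmentation = interpolate_map(mixing, geometry, source_classes)
    except Exception as exc:
        raise PipelineStageError("mapping", exc) from exc
    return RunResult(sources=sources, mixing=mixing, segmentation=segmentation, log=log)


def run_phantom_case(
    spec: PhantomSpec, config: PipelineConfig
) -> dict[str, Any]:
    """Generate one phantom and run the configured mode(s) on it."""
    grid, image, mask, gold, truth = make_phantom(spec)
    out: dict[str, Any] = {
        "grid": grid, "image": image, "mask": mask, "gold": gold, "truth": truth,
    }
    if config.mode in ("ssse", "both"):
        out["ssse"] = run_ssse(grid, mask, config)
    if config.mode in ("unsupervised", "both"):
        out["unsupervised"] = run_unsupervised(grid, config, mask=mask)
    return out


def compare_methods(
    predictions: dict[str, dict[str, np.ndarray]],
    gold_masks: dict[str, np.ndarray],
    footprints: dict[str, np.ndarray] | None = None,
) -> EvaluationReport:
    """Score every method's tumour masks against the gold standard.

    ``predictions[method][case]`` and ``gold_masks[case]`` are binary
    pixel masks.  Produces per-case records, per-method mean/sd
    summaries, and a Kruskal-Wallis test per metric across methods (when
    more than one method is present).
    """
    report = EvaluationReport()
    for method, cases in predictions.items():
        missing = sorted(set(gold_masks) - set(cases))
        if missing:
            raise ValueError(f"method {method!r} is missing cases: {missing}")
    for method in sorted(predictions):
        for case in sorted(gold_masks):
            footprint = footprints.get(case) if footprints else None
            metrics = evaluate_masks(
                predictions[method][case], gold_masks[case], footprint=footprint
            )
            report.records.append({"method": method, "case": case, **metrics})
        values = {
            m: [r[m] for r in report.records if r["method"] == method]
            for m in METRIC_NAMES
        }
        report.summaries[method] = {
            m: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for m, v in values.items()
        }
    if len(predictions) >= 2:
        for m in METRIC_NAMES:
            groups = [
                [r[m] for r in report.records if r["method"] == method]
                for method in sorted(predictions)
            ]
            report.kruskal_wallis[m] = kruskal_wallis(groups)
    return report
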
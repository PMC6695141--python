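# ssse — semi-supervised source extraction for MR spectroscopic imaging

`ssse` segments brain tumours from MR spectroscopic imaging (MRSI) grids by
embedding anatomical-image knowledge into the spectral unmixing.  It is aimed
at preclinical and clinical MRS researchers who have (a) a low-resolution
grid of voxel spectra, (b) a co-registered higher-resolution anatomical image
(e.g. T2-weighted MRI), and (c) a *partial* manual segmentation of that
image — tumour here, normal parenchyma there, uncertain areas left unlabeled —
and who want spectral sources and a pixel-resolution, colour-coded
(nosologic) tissue map that respect both the spectra and the anatomy.

## Method

Unmixing treats the spectra matrix as `X ≈ S H`: `S` holds latent source
spectra, `H` per-voxel abundances.  The package implements two routes to
this factorisation, sharing every downstream step:

**Unsupervised baseline.**  Convex non-negative matrix factorisation
(Convex-NMF) applied directly to the spectra.  Convex-NMF restricts each
source to a convex combination of the observed voxel spectra, `S = X W`
with `W ≥ 0` (columns summing to 1 after rescaling), so it tolerates
mixed-sign long-echo spectra and yields sources that read like measured
spectra.

**Segmentation-guided (SSSE).**  Three stages in front of the same
factorisation:

1. *Label transfer and posterior model.*  The pixel-level segmentation is
   voted down to voxel-level soft class proportions; a one-hidden-layer MLP
   (6 tanh units, softmax output) is trained on 75% of the labeled voxels
   against those soft targets (learning rate 0.05, momentum 0.9, weight
   decay λ = 0.01, at most 2000 epochs or mean cross-entropy < 5·10⁻³),
   giving posteriors p(c | x).
2. *Fisher-Information metric.*  The posteriors induce the local metric
   J(x) = Σ_c p(c|x) ∇log p(c|x) ∇log p(c|x)ᵀ, which stretches spectral
   directions that change class membership and collapses directions the
   classifier ignores.  Pairwise distances between all voxels (labeled and
   not) are accumulated piecewise along straight segments.
3. *Embedding and factorisation.*  Classical multidimensional scaling maps
   the FI distances to Euclidean coordinates; Convex-NMF factorises those
   coordinates, and the learned convexity weights are carried back to the
   original spectra for interpretable sources.

Either way, the mixing proportions are bilinearly interpolated up to image
resolution and arg-maxed into the nosologic map (red = tumour, blue =
normal, yellow = optional third region).  Every run models a single case;
spectra are never pooled across subjects.  An evaluation suite scores maps
against a gold-standard mask: sensitivity, specificity, Dice
`2TP/(2TP+FP+FN)`, Euclidean image distance, shape-similarity percentage,
boundary Hausdorff distance, and a Kruskal–Wallis test across methods.

Because suitable animal data are not publicly deposited, the package ships
a phantom generator with known ground truth: Gaussian metabolite peaks
(Cho 3.21, Cr 3.03, NAA 2.02, Lac/ML ≈ 1.3 ppm), an elliptical tumour with
a smooth partial-volume rim, configurable SNR, a brighter-inside-the-tumour
anatomical image, and a partial label mask that leaves the rim unlabeled.

## Worked example

```python
from ssse import PhantomSpec, PipelineConfig, run_phantom_case
from ssse.evaluation import evaluate_masks

case = run_phantom_case(PhantomSpec(seed=1, snr=10.0),
                        PipelineConfig(mode="both", seed=1))
for tag in ("ssse", "unsupervised"):
    m = evaluate_masks(case[tag].segmentation.class_mask(1), case["gold"])
    print(tag, m["dice"], m["sensitivity"], m["specificity"])
```

prints (formatted):

```
ssse         dice=0.891 sens=0.999 spec=0.952 hausdorff=5.10
unsupervised dice=0.947 sens=1.000 spec=0.978 hausdorff=2.24
```

Both modes clear the conventional Dice > 0.70 good-overlap bound on this
clean two-class phantom, and their tumour sources correlate at 0.993 —
the guidance changes *which voxels define* the sources, not their
biochemistry.  The guided mode earns its keep when the data contain
structure the annotator did not label: on phantoms with an unlabeled
confounder region (`ssse.phantom.confounder_spec`), the unsupervised
factorisation latches onto the confounder and its tumour Dice collapses,
while the guided mode is unaffected.

The same pipeline is scriptable from a shell:

```bash
ssse phantom --out data/ --seed 1
ssse run --grid data/grid.tsv --mask data/mask.tsv --mode both --seed 1 --out out/
ssse evaluate --pred out/ssse_map.tsv --gold data/gold.tsv --out report.json
```

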
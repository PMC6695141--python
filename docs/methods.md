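# Methods

## Problem setting and model

An MRSI acquisition delivers an `R × C` grid of voxels (default 10 × 10),
each holding a preprocessed magnitude spectrum of `D` points (default 692)
on a decreasing chemical-shift axis (default 4.5 → 0 ppm; point *i* sits at
`high − i·(high−low)/(D−1)`).  Spectra may be mixed-sign (long-echo
phase modulation around lactate/alanine), which rules out plain NMF.  A
co-registered anatomical image covers the same field of view at `f` pixels
per voxel side (default 10), with the voxel→pixel-block convention fixed
once: voxel `(r, c)` owns the half-open block `[rf, (r+1)f) × [cf, (c+1)f)`,
0-based, row-major.  All voting, interpolation and evaluation reuse that
single definition.

The unmixing model is `X ≈ S H` with the Convex-NMF constraint
`S = X W`, `W, G ≥ 0`, `H = Gᵀ` (after a compensating rescaling that
makes each `W` column a convex combination).  Fitting uses the standard
multiplicative updates built on the positive/negative parts of `XᵀX`,
initialised from k-means cluster indicators smoothed by 0.2 (`W`
additionally divided by cluster sizes).  These updates provably never
increase the objective; the trace is recorded and asserted in tests.

The guided variant replaces the factorisation input: soft voxel labels →
MLP posterior model → Fisher-Information (FI) pairwise distances → classical
MDS coordinates → Convex-NMF.  The convexity weights learned in the
embedded space are applied to the *original* spectra (`S = X Ŵ`), because
interpretability lives in the spectral domain; abundances come from the
rescaled `G`.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| MLP hidden units | 6 | – | small capacity for ~10² training voxels |
| learning rate / momentum | 0.05 / 0.9 | – | full-batch gradient descent on the mean loss |
| weight decay λ | 0.01 | – | L2 on weight matrices only; keeps posteriors from saturating instantly |
| stopping | mean CE < 5·10⁻³ or 2000 epochs | nats/example | the error criterion is interpreted as mean per-example training cross-entropy |
| weight init | U[−1, 1] | – | seeded; determinism is asserted bit-for-bit |
| FI segments T | 10 | – | piecewise straight-line distance; refining to T = 100 moves smooth-field distances by < 5% (tested) |
| posterior floor | 10⁻¹² | probability | guards log/division at saturated posteriors |
| MDS retention | 99% | positive-eigenvalue mass | embedding dimension rule; negative-eigenvalue mass is logged |
| Convex-NMF | max_iter 500, tol 10⁻⁶ | relative objective change | pipeline default; oracle tests raise the budget (see below) |
| k | number of segmented classes (2) | – | 3 for three-region analyses |
| train fraction | 0.75 | – | stratified by hard label (unstratified splits can starve a class at n ≈ 100) |

Spectra are L2-normalised per voxel before the MLP/FI stage (standard MRS
practice; it also keeps the tanh layer out of deep saturation at
initialisation).  Raw spectra are used for the unsupervised factorisation
and for spectral back-projection, so abundance estimates are unaffected.

## Label transfer choices

Votes are counted over *labeled* pixels only, so partial annotation does
not dilute targets.  Voxels with no labeled pixel, or with an exact
majority tie, stay unlabeled (ties are flagged separately); the
semi-supervised design tolerates unlabeled voxels, and arbitrary tie
assignment would inject noise exactly where the data are most ambiguous.
The FI distance matrix and the factorisation always cover *all* voxels —
unlabeled voxels must be embedded to be unmixed.

## The phantom generator

Each tissue class is a sum of Gaussian peaks (position, amplitude, width in
ppm) at the canonical metabolite shifts; the tumour profile has high
Cho and Lac/mobile-lipid signal and depressed NAA, normal parenchyma the
reverse.  Gaussian (not Lorentzian/Voigt) shapes keep
position/amplitude semantics with one width parameter.  The tumour is an
ellipse in continuous voxel coordinates; per-voxel abundances follow a
logistic function of the signed boundary distance (rim softness 0.35 voxel
units), creating genuine partial-volume voxels.  Noise is i.i.d. Gaussian
with σ = (strongest peak amplitude)/SNR, default SNR 10.  The anatomical
image is the pixel-resolution tumour membership plus brightness offset and
mild pixel noise; the label mask marks only pixels at least two
rim-softness units from the boundary, emulating an annotator who leaves
uncertainty out.  The optional third pattern is a normal-like profile with
a dominant 3.8 ppm resonance (amplitude 6 vs the strongest metabolite
peak's 3) — an artefact/ventricle-like structure.  Left unlabeled
("confounder"), it is deliberately strong enough that an unguided k = 2
factorisation organises around it; this realises the scenario the guided
method exists for, and the guided/unguided comparison runs on identical
data either way.

The phantoms do **not** emulate acquisition physics: no baseline or phase
distortion, no lineshape variation, no spatially correlated noise, no 3-D
partial volume, and the image-to-grid registration is exact.  Passing
tests therefore demonstrate correctness of the machinery and the expected
qualitative orderings under controlled conditions, not performance on real
acquisitions.

## Numerical choices

* Softmax logits are max-shifted; probabilities are floored at 10⁻¹²
  before logs and at 10⁻³⁰⁰ inside the loss.  Non-finite training loss
  raises a divergence error carrying the epoch index.
* FI distances are computed as directional quadratic forms
  `Σ_c (∇p_c·Δ)²/p_c` via a forward-mode pass — linear in `D`, the
  `D × D` metric is never materialised for pairwise work; one ordering per
  pair is evaluated and mirrored, so the matrix is exactly symmetric.
* Classical MDS double-centres `−½D²`, eigendecomposes, discards negative
  eigenvalues (their relative mass is logged) and keeps the smallest axis
  count covering 99% of the positive mass.  An all-nonpositive spectrum
  raises a degenerate-embedding error.
* Multiplicative-update denominators carry a 10⁻¹² zero-locking guard.
  The updates converge only sublinearly (≈ 1/iteration) toward
  zero-residual optima whose `W` has zero entries; exact-reconstruction
  oracle tests therefore run instances with pure duplicated columns or a
  hard phantom rim and an explicit 5k–20k iteration budget.  The pipeline
  default (500) is ample for the maps themselves.
* Bilinear map interpolation anchors voxel values at block centres,
  replicates edges beyond the outer centres, clips to [0, 1] and
  renormalises per pixel before the argmax.  Interpolating proportions
  (rather than hard labels) matches the smooth boundaries the method is
  meant to produce.
* Source→class matching maximises the mean per-class mixing weight over
  labeled voxels, solved exactly by permutation enumeration (k ≤ 3).
* The master seed fans out to split/MLP/factorisation seeds through
  independent `SeedSequence` children; identical (config, seed) reruns are
  bit-identical end to end.
* Evaluation runs over the MRSI grid's pixel footprint (the maps exist
  nowhere else); Euclidean distance uses binary tumour encodings, making
  distance² equal the mismatch count and consistent with the
  shape-similarity percentage; Kruskal–Wallis applies the standard tie
  correction and reports (H = 0, p = 1) with a warning when every
  observation is identical.

## Known limitations

* On *exactly noiseless* data the trained posteriors saturate and the FI
  metric collapses all within-class variation; the embedded geometry
  degenerates to (nearly) one dimension, where Convex-NMF's factors are
  underdetermined at zero reconstruction error.  The guided mode's
  spectral sources and abundances on noiseless phantoms inherit that
  ambiguity (the unsupervised route, which factorises the spectra
  directly, does not).  Measurement noise restores rank to the embedding;
  this is a property of the metric's quotient geometry, not a numerical
  bug — see the source-recovery tests.
* Multiplicative updates' sublinear tail (above) makes machine-precision
  reconstruction claims iteration-hungry.
* Whether pixel-level class probabilities should come from a first model
  on image intensities or from the mask itself is ambiguous in this
  design; the mask-derived vote proportions are used, which treats the
  manual segmentation as authoritative.
* The embedding supports `fit_transform` only: classical MDS defines
  coordinates jointly over the fitted set, so new voxels cannot be
  projected without recomputation.
* No automatic choice of k; no comparator semi-automated segmentation
  methods; no DICOM/vendor raw formats (delimited text, PNG and JSON
  only).
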
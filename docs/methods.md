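# Methods

## Model and assumptions

The segmenter treats vessels as *dark, locally linear structures of
1–15 px width on a brighter, slowly varying background*.  Three
assumptions follow, and each maps to one stage:

- the illumination bias varies on scales much larger than any vessel, so
  subtracting a wide circular-Gabor smoothing of the image (ICGF) removes
  it without deforming vessel cross-sections;
- a vessel cross-section is a trough, so the second derivative of a
  Gaussian taken across the vessel responds positively on the centerline;
  taking the maximum over rotated copies (MMSDG) finds the orientation,
  and averaging over scales σ = 1, 2, 3 covers the width range;
- vessels occupy a roughly known, dataset-stable fraction ρ of the field
  of view, so a single global threshold at the ρ-quantile of the fused,
  histogram-equalized map yields a usable coarse mask, which local
  line-support filtering and component rules then clean.

No step involves training; every parameter is a fixed number a user can
audit.

## Parameters

| key | default | unit | role |
|---|---|---|---|
| `icgf_sigma` | 24 | px | Gabor envelope scale; must exceed the widest vessel; sets the bias-estimation neighborhood |
| `icgf_freq` | 0.0 | cycles/px | radial modulation of the circular Gabor.  At σ = 24 a modulation of 0.05 drives the real-tap sum negative (≈ −0.02), which would invert the unit-sum-normalized filter, so the default is the pure Gaussian envelope; non-zero values remain configurable |
| `icgf_support` | 2·⌈3σ⌉+1 | px | kernel side; ±3σ of the envelope |
| `mmsdg_sigmas` | (1, 2, 3) | px | derivative-of-Gaussian scales → 7/13/19 px kernels (side = 6σ+1, σ integer so the rule is exact) |
| `mmsdg_angles` | 0°–150°, step 30° | deg | orientation bank; closed under 90° rotation |
| `alpha` | 0.33 | – | fusion weight of MMSDG vs ICGF (`drive` profile 0.33, `stare` 0.43) |
| `rho` | 0.081 | – | labeled vessel proportion of the FOV (`stare` 0.083); deliberately below the true vessel fraction (~0.09 on the phantoms, ~0.13 on real fundus FOVs) so that marginal, noise-prone ranks stay unlabeled |
| `eta` | 2.23 | – | elongation threshold on raw {0,1} line responses (range 0..~5) |
| `line_side`, `n_dirs` | 5, 8 | px, – | elongating-filter geometry |
| `area_min` | 40 | px | minimum surviving component area |
| `axis_ratio`, `major_max` | 0.3, 40 | –, px | speckle rule: blob-like (minor/major > 0.3) AND short (major < 40) components are removed |

The speckle rule is stated in the literature as "major/minor > 0.3",
which is vacuous (that ratio is ≥ 1 by definition); this package applies
minor/major > 0.3 — compact blobs — and exposes the literal reading via
`speckle_rule="major-over-minor"` for comparison.

## Numerical choices

- **Borders:** every convolution uses half-sample symmetric reflection;
  large kernels (the ICGF template) go through an FFT on a
  symmetric-padded copy, equivalence with direct convolution being tested
  to 1e−9 on small frames.
- **Kernel rotation:** inverse-mapping bilinear interpolation about the
  kernel center; samples fade to zero across the support edge
  (`grid-constant`), matching the per-tap definition and MATLAB's
  `imrotate`.  Consequences measured and documented: oblique 5×5 line
  kernels sum to 5.07–5.54 rather than exactly 5, and a rasterized
  straight run at a bank angle yields interior responses ≥ 3 (so the
  default η = 2.23 keeps every interior pixel) while the two endpoint
  pixels of 45° runs respond ≈ 2.17 and are dropped.
- **DC-free derivative kernels:** ∂²G/∂x² sampled on the truncated
  (6σ+1)² grid retains a residual tap sum of ≈ −4e−3; the mean is
  subtracted so constant offsets produce exactly zero response.  The
  center tap then deviates from the analytic −1/(2πσ⁴) by ~5e−4 relative.
- **Equalization:** 256-bin CDF remap restricted to the FOV (the black
  surround would otherwise dominate the histogram), with the
  `(cdf − cdf_min)/(n − cdf_min)` convention so the darkest occupied bin
  maps to 0; a constant image maps to all zeros (with a warning), which
  also defines the degenerate output of both enhancement stages.
- **Threshold ties:** the proportional threshold uses rounded integer
  intensities; the labeled count L then satisfies
  ρ|FOV| ≤ L < ρ|FOV| + hist(θ) exactly.  For ρ = 0 the darkest occupied
  bin is labeled.
- **Moment ellipse:** axis lengths are 4·√λ of the normalized second
  central moments (no 1/12 pixel-extent term); a zero major axis (single
  pixel) counts as blob-like.
- **ROC/AUC:** the sweep varies η only, on a fixed coarse mask; points
  are FPF-sorted, anchored with (0,0) and (1,1), and integrated by the
  trapezoidal rule.

## The phantom generator

`retveins.phantom` grows vessel trees as curvature-bounded random walks
from the FOV rim with probabilistic branching and width tapering, then
rasterizes each centerline point as a Gaussian cross-section whose FWHM
equals the local width (stamps combine by maximum, truncated at 3σ).
The gold mask is the half-maximum set of the rasterized depth, so a
straight width-w vessel labels exactly a w-px band.  A smooth bias field
(Gaussian-filtered white noise, max-abs-normalized), iid pixel noise, a
circular FOV with dark surround, and optional compact "lesion" disks
(kept clear of vessels, reported in a separate distractor layer)
complete the image.  One integer seed drives fixed substreams per tree,
bias, noise and lesions, so phantoms are bit-identical across runs and
adding a tree does not reshuffle earlier ones.  Tree growth stops, in
40-point increments, once the gold fraction of the FOV reaches the
target (default 0.09).

The generator deliberately omits: optic disk and fovea anatomy, vessel
texture and central reflex, structured acquisition noise (striping,
compression artifacts), and color.  Passing the packaged tests therefore
demonstrates the pipeline's behavior on idealized vasculature — bias and
iid-noise robustness, width coverage, speckle rejection — not benchmark
performance on real fundus images, which additionally depends on the
ICGF parameterization and the annotation style of the gold standards.

Two measured consequences of this idealization are worth knowing:

- On a vessel-free phantom the proportional threshold still labels ρ of
  the FOV, and the matched filters' spatial correlation clusters those
  false positives into vessel-scale components that survive refinement;
  the final false-positive load stays on the order of ρ rather than
  vanishing.
- Elongation's benefit depends on scattered false positives existing in
  the coarse mask.  With iid noise the preprocessing suppresses nearly
  all of them, so on the phantom battery the direction-union's boundary
  dilation slightly *costs* accuracy (mean −0.013) while post-processing
  still helps; on real fundus data, with structured noise, both
  components are reported to help.  The package reports both ablation
  deltas rather than asserting a direction it cannot reproduce.

## Problem sizes

Phantoms default to 256×256 px (FOV radius fraction 0.94), the battery
is five fixtures × three seeds, and η sweeps use the grid 0.1…5 step
0.1.  These sizes keep a full battery evaluation, including sweeps,
under a minute on one CPU while leaving every kernel (up to the 145-px
ICGF template) smaller than the frame.

## Known limitations

- The ICGF parameterization is an artifact choice (the originating
  literature does not pin it down); results on real data are sensitive
  to `icgf_sigma` relative to image resolution.
- Capillaries at 1–2 px width sit at the resolution limit of the σ = 1
  kernel; the capillary-rich fixture scores lowest of the battery.
- Large lesions connected to vessels merge into vessel components and
  evade the speckle rule, as the post-processing acts per component.
- The proportional threshold presumes the vessel fraction is known to
  ~±20 %; images with unusual vessel load (pathology, poor field
  placement) violate this.
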
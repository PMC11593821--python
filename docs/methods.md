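# Methods

This note documents the models, algorithmic choices and limitations of
the `hyperflux` pipeline, in the order data flows through it.

## Synthetic tissue scenes

Real acquisitions of this kind are 69-channel excitation/emission
stacks with a paired bright-field image; no public dataset exists, so
the generator (`hyperflux.synth`) emulates the statistical structure
the analysis relies on, with full ground truth for every stage.

**Geometry.** Cells are elliptical blobs (radii 4–9 px, rejection-
sampled to avoid overlap); fibres are smoothed random-walk polylines
(heading noise SD 0.15 rad/step) dilated to ~3 px width. Default
scenes are 128×128 px with 18 cells and 6 fibres; cohort scenes are
96×96 with 12 cells and 5 fibres, a desk-scale size at which every
stage's behaviour is already representative.

**Spectra.** Endmembers are skewed-Gaussian emission profiles peaked
at channels ~10 (NAD(P)H), ~30 (flavins) and ~52 (collagen), widths
6–7 channels, with a seeded 2 % channel ripple; rows are unit-L2.
Peaks must be separated by at least one width so the mixing matrix is
well conditioned (pairwise cosines ≈ 0.10).

**Abundances.** Each structure draws a mean abundance triple around
its group's effect-table entry (log-normal, CV 0.12 at ROI level),
modulated by structure type — cells ×(1.1, 1.1, 0.45), fibres
×(0.7, 0.7, 1.3), i.e. cells are metabolically dominated and fibres
collagen-rich. Within a structure, per-pixel *composition* is
Dirichlet-distributed around the structure mean (concentration 5) and
per-pixel *total* is log-normal (CV 0.20). The Dirichlet choice keeps
ROI means exactly at the effect-table values in expectation while
giving pixels the compositional spread — including near-pure collagen
fibre cores and NAD(P)H-dominated cell spots — that real tissue shows
and that makes blind unmixing identifiable. The per-pixel fluorophore
sum is capped at 0.97; the remainder is non-fluorescent background.

**Effect table.** The source observations give only directions and
significance, not effect sizes, so the defaults were chosen once so
that every encoded inequality holds with ≥ 1.5 within-group-SD
separation *after* compositional closure (relative abundances sum to
≤ 1, so boosting one fluorophore depresses the others' shares):

| group | NAD(P)H | flavins | collagen |
| --- | --- | --- | --- |
| IA-Low  | 0.24 | 0.30 | 0.20 |
| IA-Mid  | 0.26 | 0.34 | 0.25 |
| RA-Mid  | 0.40 | 0.25 | 0.28 |
| RA-High | 0.40 | 0.15 | 0.40 |

Encoded directions: NAD(P)H and redox ratio higher in both active (RA)
groups than both inactive (IA) groups; flavins lowest in RA-High;
collagen highest in RA-High. Patient-level random effects multiply the
triple by log-normal factors (CV 0.06).

**Corruption model**, applied in order: (1) additive background
fluorescence — a broad Gaussian spectrum times a smooth random spatial
field, amplitude 8 % of the tissue intensity scale; (2) multiplicative
illumination — a random quadratic field, range ±25 %, spatial mean 1,
shared across channels (vignetting is a property of the light path,
not the emission filter — hence one 2-D field broadcast over λ);
(3) Poisson resampling at a target SNR (30 dB scene / 25 dB cohort
default; the gain is set so mean tissue intensity corresponds to
10^(SNR/10) photon counts); (4) dead (all-zero) and saturated
(clamped at 4095) pixels, 0.5 % of the image. The bright-field is the
illumination field shaded by structure absorption (cells 45 %, fibres
25 %) plus Gaussian noise (SD 0.02).

**Clinical scalars** are drawn uniformly inside each group's defining
ranges (DAS-28 ≤ 2.6 inactive / > 2.6 active; VAS ≤ 10 low, 11–59
mid, ≥ 60 high; CRP < 8 mg/L inactive / > 8 active). VAS 0 is mapped
into the low bin so group assignment is total; CRP exactly 8 mg/L is
classed active with a warning, since the defining inequalities are
strict on both sides. The unobserved combinations (inactive-high,
active-low) are valid, warned-about labels that the default cohort
never generates.

**What the generator does not emulate:** optical point-spread
functions, spectral bleed-through between channels, instrument-
specific excitation/emission ladders, collagen subtypes, spatial
correlation of abundances beyond structure boundaries, and
patient-level covariate structure (age, sex, treatment). Passing tests
therefore demonstrate correctness of the algorithms under the stated
mixing/corruption model, not performance on real tissue.

## Preprocessing

Order: bad-pixel repair → background subtraction → illumination
flattening → (optional) denoising. All steps preserve shape and
non-negativity and never mix spectral channels.

* **Bad pixels**: dead = zero in every channel; saturated = at the
  saturation value in ≥ 3 channels (configurable). Repair replaces a
  flagged pixel per channel with the median of its un-flagged
  8-neighbourhood, expanding the window if necessary.
* **Background**: the default estimator is spatially varying — the
  median spectrum of tissue-free pixels (below the Otsu level of total
  intensity) gives the spectral shape; per-pixel amplitudes on the
  tissue-free set are interpolated across tissue by normalised
  convolution (Gaussian, σ = 0.12 × image size). A scalar per-channel
  median variant is available (`background_mode="median"`) but cannot
  remove a spatially varying field.
* **Illumination**: with a paired bright-field available, a 2nd-order
  2-D polynomial is fitted to per-tile 85th percentiles of the
  bright-field (structure-free bright-field pixels see the bare
  illumination; this works however sparse the fluorescent tissue is).
  Stack-only variants (tile-median polynomial fit, or large-kernel
  smoothing) are provided for densely fluorescent data. Fields are
  clipped positive and normalised to spatial mean 1. Note that
  relative abundances are invariant to any per-pixel scalar, so
  residual illumination error does not propagate into the features.
* **Denoising** uses the variance-stabilising square-root transform
  `t = sqrt(I/gain + 3/8)` (variance ≈ 1/4 independent of mean),
  Gaussian smoothing in x/y only, and the algebraic inverse. It is
  **off by default** in the chain: at the default SNRs the genuine
  per-pixel spectral texture exceeds the shot noise, and smoothing was
  measured to increase the error to the clean stack (tissue relative
  error 0.15 → 0.48 at σ = 1) while dragging blind-unmixing endmember
  cosines below 0.98. It demonstrably helps (and is tested) on smooth
  scenes at ~20 dB SNR. The photon gain, when needed, is estimated
  from the local variance/mean ratio (robust median over pixels).

## Segmentation

Performed on the bright-field alone. The image is first flattened by
the polynomial illumination fit so absorption contrast is comparable
across the field. Cells = darkest class of a 3-class multi-Otsu
threshold, hole-filled, split by watershed on the distance transform
(markers = distance maxima ≥ 5 px apart), then filtered by area
(12–2000 px) and solidity (≥ 0.8; fibre fragments are elongated and
fail this). Fibres = multi-scale Sato tubularity (σ = 1, 1.5, 2.5) of
the inverted flattened image, Otsu-thresholded **outside** a 4-px
dilation of the dark-class regions (cell rims are ridge-like and
otherwise leak into the fibre class), skeletonised, length-filtered
(≥ 15 px) and dilated back to ridge width. Cell pixels are excluded
from the fibre mask, so the two label images are disjoint; labels are
renumbered row-major by centroid so outputs are reproducible.

## Unmixing

`unmix_known` solves exact per-pixel non-negative least squares by
enumerating all support subsets (vectorised over pixels; exact because
the NNLS optimum is itself a feasible subset solution and no feasible
candidate can beat it), falling back to Lawson–Hanson for > 6
components. Relative abundances divide by (sum of raw abundances +
residual L2 norm), so per-pixel fractions sum to ≤ 1 with the
remainder interpretable as unmodelled background; they are invariant
to per-pixel intensity scaling.

`fit_blind_unmixing` is an alternating non-negative factorisation
(HALS updates) of the pixels×channels matrix under a Huber-weighted
squared loss: every 5 iterations, per-pixel weights
`w = min(1, δ/‖r‖)` with δ = 1.345·MAD-consistent scale of the
residual norms down-weight outlier pixels. Components are free to be
statistically dependent. Ten restarts by default — restart 0 seeds
from successive-projection extreme pixels, the rest from random
exponential spectra — keeping the best robust loss (ties → lowest
restart index); convergence at relative loss change < 1e-6 or 500
iterations. Endmember rows are then unit-normalised, components named
by ascending emission peak (NAD(P)H bluest, collagen reddest), and
final abundances recomputed for all pixels by exact NNLS. When a
cohort is analysed, endmembers are fitted once on tissue pixels pooled
across all patients' preprocessed stacks (so every patient shares one
spectral model) and only the NNLS step runs per stack.

Ground-truth comparisons are made on tissue (structure) pixels and in
relative (sum-normalised) form: empty pixels carry only noise, where a
relative fraction is not a meaningful quantity, and the feature
analysis never uses them.

## Features and statistics

Four features per ROI: mean relative abundances over the ROI's pixels,
plus the redox ratio NAD(P)H/flavins. ROIs with flavin abundance below
ε = 1e-3 are flagged and excluded from ratio-based statistics (the
ratio is undefined, not zero or infinite). Statistics run at the ROI
level by default — each cell/fibre is an observation, matching scatter
plots where symbols are individual cells — with a patient-level
aggregation option; ROI-level inference pseudo-replicates patients and
should be interpreted accordingly. Group comparisons use the
two-sided Mann–Whitney U test with midrank ties: exact null
distribution when the pooled sample is tie-free and ≤ 16, otherwise
the normal approximation with tie-corrected variance and continuity
correction. (At 8+8 the continuity correction itself shifts mid-range
p-values by up to ~0.011, which bounds the achievable exact/asymptotic
agreement.) P-values are reported raw — significance is declared at
p < 0.05 with */**/*** stars at 0.05/0.01/0.001 — and a Holm
step-down option exists but is off by default.

## Discrimination

Features are z-scored internally, making the projection and classifier
exactly invariant to affine rescaling of any feature. With two groups
the canonical analysis has a single discriminant variate:
`w₁ ∝ (S_W + λ·tr(S_W)/p·I)⁻¹ (m₂ − m₁)` with shrinkage λ = 1e-3 to
stabilise the within-scatter inverse at small n. The 2-D plot idiom is
preserved by taking axis 2 as the leading principal direction of the
within-group residual orthogonal to axis 1 — it adds spread, not
discriminative information. Ellipses are 1 SD (eigendecomposition of
the projected 2×2 covariance); axis signs make the first non-zero
loading positive. The linear classifier scores along w₁ with a
midpoint threshold. ROC curves sweep unique scores with tied scores
stepped simultaneously, so AUC equals the Mann–Whitney statistic
U/(n₊·n₋) exactly on tie-free data.

Two evaluation modes: **resubstitution** (in-sample, mirroring the
apparent evaluation of the original analysis) and
**leave-one-patient-out** (all ROIs of one patient held out per fold),
which is the recommended mode because ROIs of one patient are
correlated and in-sample evaluation inflates AUC. The chance-level
check of a zero-effect cohort is run leave-one-patient-out on an
exchangeable null (identical effect means, no patient random effect):
with patient-level clustering retained, the null AUC of a 22-patient
cohort fluctuates far outside any fixed band — a small-sample property
of clustered data (including the known LOPO "anti-learning" bias), not
of the classifier.

## CMYK autoencoder

A fully connected 69→16→4→16→69 network: ReLU hidden layers, sigmoid
bottleneck (codes in [0,1]⁴), softplus output (non-negative spectra).
Loss = mean squared reconstruction error + α × (negative Fisher ratio
of the bottleneck codes between two patient groups), α = 0.1 by
default; with a single group the penalty is disabled and the model is
a plain autoencoder. Training: Adam (lr 3e-3), batch 256, 60 epochs,
up to 50 000 tissue pixels, all randomness from one seed (fixed
initialisation and data order ⇒ bit-identical retraining). The four
bottleneck units map to (C, M, Y, K) in fixed order after a
per-channel min–max rescale over the training codes; rendering uses
the naive conversion R=(1−C)(1−K), G=(1−M)(1−K), B=(1−Y)(1−K). Colour
assignment is a convention: the displayed hues are not comparable
across independently trained models.

## Pipeline and reproducibility

`run_pipeline` executes synth → preprocess/segment/unmix → features →
discriminate → encoder from a single config; any stage failure aborts
with the stage named. One global seed fans out to per-stage seeds by
hashing the stage name (BLAKE2, < 2³¹), so stages can be re-run in
isolation and reproduce a full run bit-for-bit; the manifest records
config, seeds, outputs, QC numbers and timings. Two runs with the same
config and seed produce byte-identical feature CSVs.

## Numerical and degenerate-input conventions

Zero pixels unmix to zero abundances; all-zero channels leave the
illumination field at 1; an all-flagged image cannot be repaired
(error); empty bright-fields segment to zero ROIs; identical samples
give U = n²/2 and p = 1; degenerate scatter (zero within-group
variance or equal means) flags the projection/classifier and falls
back to the mean-difference direction; endmember sets are validated
to be non-negative, non-zero and full rank before NNLS.

## Known limitations

ROI-level statistics pseudo-replicate patients; the blind
factorisation's identifiability depends on compositional spread that
real tissue may or may not provide; the collagen component cannot be
split into subtypes (their spectra overlap); resubstitution AUCs are
optimistic and leave-one-patient-out should be preferred for any
claim about generalisation; and all quantitative guarantees are
statements about the synthetic model above, at the desk-scale sizes
stated, not about instrument data.
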
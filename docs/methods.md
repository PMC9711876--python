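# Methods

## The single-sample AR activity score

The score treats a signature panel as one group and all remaining quantified
genes as the other, and asks how completely the panel dominates the
within-sample expression ranking. With midranks for ties, the U statistic is
computed via the rank-sum identity `U = R_panel − m′(m′+1)/2`, which is
algebraically equal to the explicit pairwise count with 0.5 credit per tie;
the test suite verifies this equivalence against brute-force enumeration to
1e-12 on a thousand random matrices. `s = U/(m′·n)` is the AUC form of the
statistic: it is the only normalisation that makes a fixed cutoff such as
0.6 meaningful across samples with different gene counts, and it gives the
exact complement symmetry `s(panel) = 1 − s(background)`.

Properties that follow and are tested: `s ∈ [0, 1]`; bit-identical
invariance under any strictly increasing per-sample transform (hence
sequencing-depth independence); null centring at 0.5 for random panels on
i.i.d. data.

Design choices:

- **Background set** — all non-panel genes in the matrix, unfiltered by
  default. An optional `min_tpm` floor removes low-abundance background
  genes (panel genes are always retained); because it changes `n`, it must
  be requested explicitly and is logged.
- **Gene matching** — case-insensitive after whitespace stripping; unmatched
  panel genes are dropped with a warning and `m′ < m` is reported.
- **Cutoff** — strict (`score > 0.6`), configurable; the responder
  thresholds in the clinical module are by contrast inclusive, and this
  asymmetry is deliberate.
- **Default panel** — the identities of the canonical 10-gene AR target
  panel differ between studies; the shipped file is a clearly labelled,
  configurable stand-in (a widely used 10-gene AR signature), not a claim
  about any particular study's list.
- **Diagnostics** — leave-one-gene-out re-scoring (the omitted gene rejoins
  the background) probes single-gene dominance; the pairwise Pearson matrix
  of panel-gene expression probes colinearity; an optional covariate
  correlation (e.g. against AR protein OD) checks that the score carries
  information beyond protein abundance.

## IHC quantification

The physical model is Beer–Lambert absorbance. OD uses log base 10; when no
white reference is supplied it is estimated per channel as the 99th
percentile intensity, which is robust to debris and dust. Intensities are
clamped to ≥ 1 count before the log, so a zero pixel cannot produce an
infinite OD; pixels brighter than the reference clamp to OD 0.

Stain separation solves the least-squares problem `OD ≈ C·V` for the 2–3
unit-norm stain colour vectors `V` (defaults: the classical hematoxylin and
DAB calibration vectors) via the pseudoinverse, clipping negative
concentrations to zero. Collinear stain vectors are rejected at model
construction. On clamp-free synthetic images the unmix/recompose round trip
is exact to numerical precision (tested < 1e-6).

Compartment segmentation is a per-pixel random forest (50 trees, fixed
seed, training pixels subsampled to 60k) over 8 features: the 3 OD
channels, the unmixed stain concentrations, and Gaussian-smoothed OD
(σ = 2 px). This deliberately uses pixel-level features only — desk-scale
training on a handful of labelled slides, persisted with a JSON metadata
sidecar. Tumor cellular area is defined as nucleus ∪ cytoplasm; stroma
outside the classifier's cell classes is excluded from "whole cell" means.

H-scores bin per-cell mean chromogen OD at configurable absolute thresholds,
default (0.15, 0.40, 0.80): ≤ t₁ → 0, (t₁,t₂] → 1+, (t₂,t₃] → 2+,
> t₃ → 3+. Absolute OD thresholds were chosen over data-driven tertiles as
the default because they are stable under resampling and make planted-value
recovery well defined. Cells are connected components of the nucleus mask;
for nuclear markers (MYC, Ki-67) intensity is averaged over the nucleus
only, while `compartment="cell"` assigns each cytoplasm pixel to its nearest
nucleus for membranous/cytoplasmic markers.

## Clinical endpoints

- Responder rule: PSA percent change ≤ −50 **or** tumor-volume percent
  change ≤ −30 (inclusive thresholds, literal reading of "at least"); when
  volume is unavailable the call is PSA-only and flagged. The rule is
  monotone: lowering the on-treatment PSA can never revoke responder status
  (property-tested).
- Kaplan–Meier and the two-group log-rank test are delegated to lifelines
  behind this module's interface; at tied times events precede censorings
  (the standard convention). The test suite checks the estimator against a
  hand product-limit computation and the log-rank statistic against a manual
  observed-minus-expected risk-table tabulation, keeping implementation and
  oracle independent.
- Welch/paired t, chi-squared proportion tests and Pearson correlations go
  through scipy; p-values are two-tailed and reported unadjusted (a
  Benjamini–Hochberg helper is available but off by default, matching the
  single-comparison style of small paired-biopsy studies).
- `tumor_volume` uses the caliper coefficient 0.5236 = π/6 to 4 decimals;
  `predicted_population_response` multiplies biomarker prevalence by the
  conditional response rate and rounds half-up to one decimal, which is the
  convention needed for 36.5% × 70% to print as 25.6%.

## The synthetic cohort generator

The generators define the study conditions under which the pipeline is
validated; all are pure functions of (config, seed).

- **Expression**: i.i.d. Gaussian log2 abundance (mean 3, sd 2) rather than
  negative-binomial counts — legitimate here because the score is rank-based
  and unit-agnostic, so only the ordering matters. AR-high samples receive a
  +δ log2 shift on the panel genes (default δ = 2). Defaults: 5,000 genes,
  50 samples, AR-high fraction 0.365 (the biomarker prevalence scale
  reported for mCRPC cohorts).
- **Paired treatment effect**: AR mRNA is multiplied by 0.5 in every sample
  (universal on-treatment AR downregulation). The MYC log2 change is a hinge
  in the baseline score, −β·max(0, s − 0.6) + ε with β = 5 and ε ~ N(0,
  0.3²), encoding the observation that MYC suppression occurs only above the
  biomarker cutoff. The 8q24 co-regulated transcripts (PCAT1, PVT1) carry
  the same deterministic hinge signal plus their own independent noise, so
  their change correlates with the MYC change exactly when suppression is
  planted and decorrelates under β = 0.
- **Survival**: exponential event times (analytically tractable for
  size/power checks), baseline hazard 0.058/month (≈ 12-month median) for
  the low-activity stratum and baseline/HR for the high stratum, HR = 3 by
  default; independent exponential censoring with its hazard set so the
  expected censored fraction equals the configured rate (default 0.2).
- **IHC slides**: non-overlapping nuclear disks (radius 5–8 px) with 4-px
  cytoplasm annuli on a 160×160 canvas; per-compartment hematoxylin and DAB
  concentrations are planted, rendered through the same stain vectors the
  unmixing uses (so round-trip tests isolate segmentation error), inverted
  through Beer–Lambert, and degraded with 1% Gaussian intensity noise. For
  H-score recovery, per-cell DAB concentrations are drawn from discrete
  classes centred inside the default bins (0.05/0.25/0.60/1.00), so
  boundary-pixel effects cannot flip a cell's bin.
- **PDX calipers**: exponential growth/regression phases — control grows at
  0.03/day; continuous androgen regresses at 0.04/day until resistance onset
  at day 150 (≈ 5 months) then regrows; the alternating androgen/AR-inhibitor
  arm switches every 21 days and stays suppressed. Isotropic caliper
  dimensions derive from the 0.5236·L·W·H volume formula.

What the generators do **not** emulate: gene–gene correlation structure,
compositional (library-size) artefacts, batch effects, realistic nuclear
morphology or staining heterogeneity within compartments, and informative
censoring. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted effects under clean conditions,
not robustness to every real-data pathology.

## Problem sizes and numerics

The validation suite uses desk-scale sizes chosen as the package's own
convention: 1,000 random matrices (≤ 50 genes, ≤ 10 samples, integer-valued
to force ties) for oracle equivalence; 10,000 random 10-gene panels on a
5,000-gene sample for null calibration (tolerance ±0.01 on the mean);
n = 50/50 cohorts for planted-shift recovery (AUC ≥ 0.9); 500 simulations
per condition for log-rank size (0.05 ± 0.02) and power (≥ 0.80 at HR 3,
n = 50/arm); 160–192 px slides with 20–25 nuclei for IHC recovery (N:C
ratio within 10%, H-score within 10 points, IoU ≥ 0.8 on a held-out slide).
Scores are exact rational arithmetic in floating point (rank sums), so
monotone-invariance checks assert bit identity, not approximate equality.
Degenerate inputs fail loudly: empty backgrounds, unmatched panels,
single-class training labels, empty compartments (flagged N:C), zero-event
survival comparisons, and non-positive baselines all raise rather than
returning silent zeros.

## Known limitations

- The default gene panel is a stand-in; scores are only comparable across
  studies when the same panel is used.
- The pixel classifier is trained per staining protocol; a model trained on
  one chromogen pairing will not transfer to another.
- The hinge form of MYC suppression is a deliberate simplification of a
  threshold observation; real dose–response around the cutoff is unknown.
- No Cox regression or multivariable modelling; comparisons are two-group
  nonparametric by design.
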
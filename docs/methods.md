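# Methods

## Overview

`oscnet` implements an oscillation-resolved, graph-theoretic nodal
analysis of resting-state functional brain networks.  Per-subject ROI
BOLD time series are preprocessed, split into canonical oscillation
bands, turned into binarized connectomes over a sparsity grid, and
summarized by threshold-free nodal metrics whose group differences,
clinical correlates and discriminative value are then tested.  Because
raw clinical resting-state cohorts of this kind are rarely shareable,
the package ships a first-class synthetic cohort generator whose
defaults encode the acquisition and demographic structure of an
early-to-middle-stage Parkinson study (three groups EPD/MPD/NC; 112
ROIs; 205 volumes at TR = 2 s), with plantable band-specific effects for
validating the entire stack end to end.

## Oscillation bands

The BOLD spectrum at TR = 2 s (Nyquist 0.25 Hz) is divided into five
bands: slow-6 [0, 0.01), slow-5 [0.01, 0.027), slow-4 [0.027, 0.073),
slow-3 [0.073, 0.198) and slow-2 [0.198, 0.25] Hz.  Connectomes are
constructed within slow-5/4/3 only — slow-6 is dominated by drift and
slow-2 by high-frequency physiological noise.  A conventional broadband
window [0.01, 0.1) is available as a control band.  Band intervals are
half-open over DFT bins; the lowest band of a partition keeps the DC bin
and the highest keeps the Nyquist bin, so the five filtered signals sum
exactly to the input (verified to 1e-8 relative RMS).  Filtering is an
ideal rectangular FFT filter with no taper: this makes the band
partition exact and testable, at the price of ringing that a tapered
filter would trade for band leakage.

## Preprocessing

Stages run in this order per subject:

1. **Initial-volume discard** (default 10 of 205 volumes, leaving 195):
   removes the unstable initial scanner signal.
2. **Nuisance regression**: Friston's 24-parameter motion expansion (6
   rigid-body parameters, their one-frame lags, and both sets squared)
   plus mean white-matter and CSF signals, with an intercept.
   Near-duplicate columns are pruned; a rank-deficient design raises.
3. **Linear detrending** per ROI.
4. **Band-pass filtering** into each analysis band.
5. **Motion scrubbing** by deletion: frames whose framewise displacement
   (Power's formula; rotations converted to arc length on a 50 mm
   sphere) exceeds 0.5 mm are deleted.  An optional augmentation policy
   flags one frame back and two forward.

The placement of scrubbing *after* band-pass filtering is a deliberate
design choice.  Deleting frames from the broadband series before the
FFT band split smears band-limited structure across band boundaries;
in simulation this injected a planted slow-5 group effect into the
slow-4 contrast at many times the null rate.  Filtering first and then
deleting the flagged frames from each band-limited series preserves the
spectral separation that the whole analysis is predicated on.  The
alternative order is available via
`PreprocessConfig(scrub_order="before_bandpass")`.

Subject-level exclusion rules: maximum translation > 2 mm or rotation >
2 degrees; MMSE at or below the literacy-specific cutoff (17 illiterate,
20 grade-school, 23 junior-high and above — a score *equal* to the
cutoff is excluded, reading the thresholds literally); and strictly more
than 1/3 of frames removed by scrubbing (65 of 195 frames is retained,
66 is excluded).  Rules are evaluated independently, so QC is idempotent
and order-free; every violated rule is recorded.

## Connectome construction and nodal metrics

Nodes are the 112 regions of a Harvard-Oxford-style parcellation (48
cortical + 7 subcortical structures per hemisphere, plus left/right
brainstem).  Edges are Pearson correlations between band-limited ROI
time courses, Fisher r-to-z transformed (r clipped to 1 - 1e-7 first).
Each weighted matrix is binarized at sparsities 5%..50% in steps of 5%:
at sparsity S the round(S x 6216) largest *signed* z values become
edges.  Ranking by signed value means strong negative correlations are
never selected — the prevailing convention for binarized connectomes;
because selection is rank-based the graphs from r and z are identical,
and the edge sets are nested across the grid.  Ties are broken by
lexicographic node index for cross-platform reproducibility; the edge
count uses round-half-away-from-zero.

Per graph we compute unnormalized nodal degree, unnormalized betweenness
centrality (Brandes accumulation, computed via igraph's C
implementation and cross-checked in the test suite against exhaustive
shortest-path enumeration on all 142 connected graphs of at most six
nodes), and nodal efficiency (mean inverse BFS distance, with 1/inf = 0
for unreachable pairs; no largest-component restriction).  Betweenness
normalization is a constant factor at fixed N and cannot change group
inference.  Each metric's curve over the grid is integrated by the
trapezoid rule into a per-node AUC; the trapezoid (rather than a
rectangle sum) is grid-refinement consistent, and on this uniform grid
the two differ by a fixed linear map that leaves inference ordering
unchanged.

## fALFF

From the unfiltered (broadband, post-scrub) series, the single-sided
DFT amplitude spectrum is computed per ROI with the DC bin excluded
everywhere.  ALFF of a band is the amplitude sum over the band's bins;
fALFF divides by the amplitude sum over the entire detectable range
(0, Nyquist], so the fALFF values of a disjoint band partition sum to
exactly one.  fALFF is computed at ROI level (the package operates on
ROI time series; voxelwise maps would require registration machinery).
Within-subject z-standardization across ROIs uses the n-1 denominator.

## Group inference

Per node, metric and band, the AUC is regressed on a two-group
indicator plus covariates of no interest (age, sex as a single
indicator, and head motion summarized as mean FD over retained frames —
the field's default scalar).  The two-sided t test on the group
coefficient is thresholded at p < 1/112 (approximately 0.009), i.e. one
expected false positive per 112-node analysis; with several pairwise
group contrasts the threshold is additionally Bonferroni-divided.
Thresholds are applied strictly (<, not <=).  Constant covariates
(e.g. single-sex subsamples) are dropped as collinear with the
intercept rather than failing the fit.  Null calibration is verified by
simulation: across replicate null cohorts the mean number of
significant nodes per analysis is statistically compatible with one.

Clinical screening takes each intergroup-significant node and computes
partial correlations of its AUC with the UPDRS motor score (age, sex,
motion regressed out), then with the tremor subscale (items 20 + 21)
controlling the akinesia/rigidity subscale (items 22-27 + 31) and vice
versa; p-values use t with df = n - k - 2 and Bonferroni correction over
the screened family.

Discrimination fits a logistic regression on selected nodal AUCs.
Backward elimination (drop the largest Wald p while it exceeds 0.05) is
the default, since the original variable-selection algorithm is not
specified; an "enter" mode fits all candidates.  Perfect or
quasi-separation (runaway coefficients) falls back to an L2-penalized
fit, flagged in the result.  The ROC curve is a threshold sweep over the
unique scores, its AUC the trapezoidal integral (identical to the
normalized Mann-Whitney U), and the operating point maximizes Youden's
J = sensitivity + specificity - 1 with ties resolved toward higher
specificity.

## Synthetic cohort generator

Per subject and band, every ROI is a unit-variance mixture of a global
band-limited factor (baseline latent correlation c0 = 0.2, with a small
per-subject jitter of 0.03), optional planted-effect factors, and
idiosyncratic band-limited noise.  Band components are synthesized by
applying the package's own ideal band-pass to white noise on the
*post-discard* time grid, so planted structure aligns exactly with the
analysis bins; the 10 initial volumes are matched-variance noise with a
decaying saturation transient, which is precisely what the discard stage
exists to remove.  Band powers are equal for slow-5/4/3 and reduced for
slow-2 (0.25), consistent with an approximately 1/f spectrum in which
these three log-spaced bands carry similar power.  On top come white
measurement noise (sd 0.6), a per-ROI linear drift, occasional
single-frame motion spikes (probability 0.015 per frame) with random-walk
rigid-body motion calibrated to the target mean FD, and small
white-matter/CSF/motion leakage into the ROI signals so that nuisance
regression has real work to do.

Planted effects come in two mechanisms, both specified on the latent
correlation scale and both strictly band-limited:

* **increase** — hub nodes couple to a partner community (default 70
  nodes spread over the atlas, partner loading 0.35) through a shared
  latent factor, raising each hub-partner latent correlation by exactly
  `connectivity_delta`.  A uniform "hub to everyone" increase is
  geometrically infeasible above sqrt(c0) - c0 (the matrix stops being
  positive semidefinite), which is why the community construction is
  used.
* **decrease** — hub nodes are detuned from the band's global factor,
  lowering their latent correlation with *all* other nodes by exactly
  `connectivity_delta` (feasible up to c0).  A community-style decrease
  saturates the nodal degree response; detuning yields a graded,
  invertible severity-to-metric mapping, which the clinical-link
  machinery needs.

Each affected subject draws an effect-strength multiplier (mean 1, sd
0.2 by default; clipped to the feasible range).  A `MotorLink` maps that
multiplier to a motor subscale target (akinesia/rigidity by default), so
the generated clinical score is causally driven by the same latent
severity that perturbs the connectome — the planted association that the
partial-correlation screen must recover.  Infeasible deltas (latent
correlations leaving (-1, 1), loadings exceeding unit variance, or
decreases exceeding the baseline) are rejected at spec construction with
a message.

Clinical covariates (age, sex ratio, education, MMSE, head motion,
UPDRS motor/subscale distributions, Hoehn-Yahr stages, disease duration)
default to values typical of an early/middle-stage Parkinson cohort,
differing by group.  UPDRS items 18-31 are generated integer-valued
(0-4 per item) to match the subscale targets.

**What the generator does not emulate:** hemodynamic response shape,
spatially structured parcel geometry, realistic artifact spectra beyond
linear drift and motion/nuisance leakage, non-Gaussian BOLD marginals,
and any spatial smoothness between neighbouring ROIs.  Passing tests
therefore demonstrate that the *pipeline* is correct and calibrated
under its stated assumptions — not that identical effect sizes would be
recovered from real scanner data.

## Replicated simulation studies and problem sizes

Three studies (in `oscnet.experiments`) characterize the stack:

* **Null calibration** — replicate two-group null cohorts (15/group in
  the default test configuration), full pipeline in one band, all three
  metrics; the mean count of nodes passing 1/112 per analysis is
  compared against one with an empirical standard-error margin.
* **Hub detection** — a +0.25 slow-5 effect at the putamen-analog nodes
  in the middle-stage group only, at the study's group sizes (49
  affected / 36 controls); detection requires both hub nodes significant
  with the correct sign in slow-5; slow-4/slow-3 contrasts at the same
  nodes estimate off-band leakage.  Measured: ~95% in-band detection
  with off-band rates a few percent (null ≈ 2%).
* **Motor-association recovery** — a slow-3 occipital decrease (delta
  0.15) with per-subject severity (sd 0.4, matching the large clinical
  spread of akinesia/rigidity scores) driving the AR score (slope 25,
  noise sd 3); recovery requires a Bonferroni-significant negative AR
  partial correlation with no tremor association.

Replicate counts in the test suite (40/40/30) and acceptance script
(30/30/25) are chosen so the full suite completes in a few minutes on
one CPU; the detection-rate estimates are binomial proportions whose
precision scales accordingly.  Effect sizes and the severity-link slope
are calibration knobs of the synthetic design — the study they emulate
reports no latent-scale effect magnitudes — chosen once so that the
planted effects sit clearly above the detection threshold at the
emulated sample sizes, and documented here.

## Numerical choices and degenerate inputs

* Fisher transform clips |r| at 1 - 1e-7; diagonals are excluded from
  all edge operations.
* Zero-variance ROIs are rejected by name before correlation; constant
  rows are detected with a relative tolerance (exact float zero is not
  reliable after mean subtraction).
* A response fully absorbed by a covariate makes the contrast t a 0/0
  ratio; the coefficient (exactly zero) is the well-posed quantity.
  Similarly, a partial correlation whose arguments are fully explained
  by the covariates returns r = 0 by explicit convention rather than
  floating-point accident.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical specs produce
  byte-identical cohorts and pipeline outputs.

## Known limitations

* Negative-correlation handling at binarization (excluded from
  selection by signed ranking) follows toolbox convention; an
  absolute-value variant is not implemented.
* Global-signal regression is intentionally absent, matching the listed
  nuisance set.
* The logistic variable-selection rule and the scrubbing parameters are
  under-specified in the emulated protocol; the defaults here (backward
  elimination at 0.05; FD threshold 0.5 mm, no augmentation) are
  documented choices, each configurable.
* ROI-level fALFF is not a substitute for voxelwise fALFF maps with
  cluster-level correction.
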
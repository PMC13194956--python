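# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic validation does and does not
establish.

## Measurement model

An A-scan's outer-retinal reflectivity is summarised by two peaks: the
ELM (shallower) and the EZ (deeper).  A measurement window of
15 px (lateral) × 40 px (axial) is averaged laterally to one mean grey
value per row — the axial profile — and the two band peaks are read off
that profile.  rEZR is the ratio of the raw EZ peak value to the raw ELM
peak value.  Peak heights are raw profile values, not sub-pixel
interpolations and not background-subtracted, matching how a reader
documents peak intensities from a plot profile.  Because both peaks sit
on the same additive background and scale together under global
brightness changes, the ratio is invariant to multiplicative intensity
scaling (verified to <1% over scale factors 0.5–1.5, pre-quantisation).

### Peak detection

Grading in practice is manual; an automatic reading needs two
parameters that are therefore package conventions, both config-exposed:

* **minimum prominence, 5 grey values** — small enough to keep genuine
  bands under 0.5× brightness scaling, large enough to reject
  quantisation-level ripple;
* **minimum peak separation, 10 µm** — below the ELM–EZ anatomical gap
  (~25–35 µm) but above the axial resolution (3 µm), so the two bands
  are never merged and speckle side-lobes are.

Among qualifying local maxima, the pair with the largest summed
prominence wins; ties break towards the shallower pair.  The shallower
member is always assigned to the ELM (`elm_row < ez_row` is enforced).
Profiles with fewer than two qualifying peaks are recorded as
`peak_failure`, never silently dropped.  No smoothing is applied by
default; a moving-average flag (width 3 rows) exists but is off
everywhere in the shipped analyses.

### ROI placement rules

Locations: foveola; nasal/temporal (horizontal scans) and
superior/inferior (vertical scans) at 500/1000/2000 µm; peripapillary at
3000 µm nasal, horizontal scans only — 8 windows per horizontal scan,
7 per vertical.  A window over a vessel shadow or layer disruption is
shifted in 1-px steps to the nearest fully valid centre within ±100 µm
(the quoted bound is a bound, not a step size); equidistant candidates
prefer the fovea-ward side, keeping the eccentricity error one-sided.
If no valid centre exists the location is excluded.  The implementation
is checked against a brute-force enumeration oracle over all candidate
centres.

Conventions the imaging protocol leaves open, fixed here and
configurable: rows are axial with row 0 on the vitreous side; for right
eyes nasal lies towards decreasing column index (mirrored for left
eyes); superior lies towards decreasing column index on vertical scans.
The fovea column and the µm-per-pixel scales are explicit metadata —
never inferred from the image.  Validity masks come from annotation or
phantom truth; an automatic dark-column detector is provided but never
applied silently.  The peripapillary window is measured on all three
horizontal scans and averaged like every other location, and foveola
values pool horizontal and vertical scans — both choices are defaults
where the protocol is silent.

## Aggregation

Scan replicates (3 per orientation) are averaged per location first,
using only `ok`-status measurements.  Then: rings (central 1 mm, inner,
outer) take the mean over valid subareas of one eccentricity — values
within a ring are assumed similar, so partial data is tolerated;
quadrants pool one direction across the three eccentricities and are
complete-case — values change with eccentricity, so a missing subarea
would bias the mean; the total area is the unweighted mean of the three
ring values and requires all three (each ring may itself rest on partial
subareas — the corner case is not specified anywhere, and requiring the
three ring values is the conservative reading of "mean over the three
rings").  All rules are tested exhaustively over every presence pattern
against a brute-force oracle.

## Statistical models

* **Location models** (one per region, 10 in the full analysis):
  `rEZR ~ group + duration + age + gender + eye_side + (1 | patient)`,
  REML.  Group is tested with a type III F-test; the three pairwise
  contrasts are differences of adjusted means (with additive covariates
  these are exact coefficient contrasts), reported without multiplicity
  adjustment.  Contrasts are always computed and carry a `gated` flag
  when the overall F-test p ≥ 0.05, so the conditional reporting rule is
  preserved without making outputs data-dependent.
* **Ring model**: per-scan ring values,
  `rEZR ~ ring * group + covariates + (1 | patient) + (1 | patient:eye)`.
  The eye-within-patient intercept absorbs the correlation among the
  three replicates per eye.  Main-effect type III tests average over the
  other factor's levels; within-stage ring contrasts use Tukey
  adjustment for a family of three via the studentized-range
  distribution (so the adjusted p never falls below the unadjusted one).
* **VA models**: logMAR on total-area (model 1) or foveolar (model 2)
  rEZR with a patient intercept, univariable and adjusted for age,
  duration and DR stage.

Location models use one scan-averaged value per eye; the ring model uses
scan-level rows — the former matches per-eye sample sizes in grouped
reporting, the latter is what the nested random effect exists for.
Complete cases are used per model and the dropped-row count is reported
next to the eyes (patients) counts, so covariate-driven attrition
(disease duration is the usual culprit) is visible.

### Small-sample inference

Fitting goes through statsmodels `MixedLM`; the optimum is then polished
with a bounded quasi-Newton pass on the package's own restricted
log-likelihood (variance-component scale, analytic per-cluster batching)
so that the curvature used below is evaluated at a genuine stationary
point.  Satterthwaite denominator degrees of freedom are computed from
first principles: for a contrast c,
`df = 2·Var(c'β)² / (g' A g)` with g the finite-difference gradient of
`Var(c'β)` in the variance parameters and A the inverse curvature of the
restricted likelihood.  Multi-df F-tests eigendecompose `L C L'`, give
each eigen-contrast its own df, and combine them through
`df_den = 2E/(E−q)`, `E = Σ ν_j/(ν_j−2)`.  On identical data this
reproduces the reference R stack (lme4/lmerTest/emmeans) to at least
four significant digits in estimates, standard errors, dfs, type III
F-tests and Tukey-adjusted contrasts (frozen-oracle tests in
`tests/test_stats.py`).  Degenerate inputs are handled explicitly: a
constant response short-circuits to zero contrasts with a warning; a
variance component pinned at zero is flagged as a singular fit, and
non-positive-definite curvature at a boundary falls back to its PSD part
(dfs become large, hence conservative, rather than undefined).

## Synthetic data

### Phantom

Each column carries two Gaussian bands over a uniform background:
ELM amplitude 120, EZ amplitude rising 150→190 with eccentricity
(saturating at 2000 µm — reproducing the perifoveal EZ reflectivity
maximum), band σ 6 µm, ELM–EZ gap 30 µm, background 20, sampled at
3 µm axial × 10 µm lateral on a 320 × 1024 grid, optionally attenuated
by vessel-shadow intervals, plus i.i.d. Gaussian noise, clipped and
rounded to 8 bit.  Defaults make the gap an integer number of pixels so
both bands share the same sub-pixel sampling loss and the sampled ratio
equals the analytic one.  The foveal pit raises the bands by up to
120 µm over the central ±500 µm with a cos² radial profile — chosen over
a parabola because its slope vanishes at the foveola and at the 500 µm
rim, so no planned measurement window sits on a steep band slope (a
parabolic pit has its maximal slope, ~0.5 µm/µm, exactly at 500 µm,
which would smear the 15-px-averaged profile beyond recognition).

Ground truth is defined on the pixel-sampled noiseless image (shadow
attenuation applied, before noise and quantisation): per column, the
true peak values — including the background pedestal, exactly as a
profile reader sees them — and their ratio.  What the phantom does *not*
model: speckle statistics, the full layer stack, device PSF, curvature
and motion.  Phantom-based tests therefore establish that the
measurement chain is correct and noise-stable, not that it is robust to
every property of clinical scans.

### Cohort simulator

One row per scan × eye × region:
`rEZR = region mean + group effect + (group × region) effect +
covariate effects + patient intercept + eye intercept + residual`.
Group sizes are eyes per DR stage; with a patient count given, the
number of two-eye patients is forced exactly (largest-remainder
allocation across groups; both eyes of a patient share the group — the
study design does not constrain this and within-patient stage
concordance is the common case).  Covariate defaults are pooled cohort
magnitudes: age 62 ± 9 y, diabetes duration 15 ± 8 y (truncated at 0),
27% female; an optional missing-at-random rate (default 0) emulates
missing duration.  All randomness flows from one explicit integer seed
per call; identical specs are bit-identical.

## Validation design and problem sizes

* **Parameter recovery** — 200 cohorts per check at the study's exact
  size (64 eyes / 44 patients split 17/33/14; the peripapillary check
  at its reduced 50 eyes / 34 patients, split 13/26/11 by proportional
  rounding since only the totals are reported), patient SD 0.15 and
  residual SD 0.10 on the eye-level scale, covariate effects zero, with
  the published contrasts injected as truths.  The mean recovered
  contrast must sit within ±0.03 rEZR units of its truth (the per-seed
  SE is ≈0.08, the 200-seed mean SE ≈0.005).  The ring-model check uses
  scan-level data with variance components 0.02 / 0.0025 / 0.01
  (patient / eye / residual) and the published within-stage ring steps;
  the VA check injects the published slope with rEZR SD 0.2, patient SD
  0.05, residual SD 0.08.
* **Calibration** — 1000 null replicates at 500 patients (the study's
  eyes-per-patient ratio preserved) for the group F-test type-I error,
  and CI coverage of the outer-ring recovery replicates.  200 and 1000
  replicates keep the full suite near ten minutes on one CPU while
  leaving the Monte-Carlo SE of a rejection rate at ~0.007 — tight
  enough to detect real miscalibration, but note that the acceptance
  bands ([0.04, 0.06], [0.93, 0.97]) are only ±1.3–1.5 of those SEs
  wide, so a perfectly calibrated implementation still leaves a band
  with roughly 15–20% probability on any fixed seed.

## Known limitations

* Axial ROI placement is hint- or intensity-driven; there is no layer
  segmentation, so severely disrupted outer retina can defeat the
  automatic placement (it is designed for phantom and lightly degraded
  data; clinical use would supply hints from manual placement).
* The Satterthwaite machinery assumes the REML optimum is interior;
  at variance boundaries the dfs degrade gracefully but the F-test is
  then conservative.
* Quadrant analyses and NPDR sub-stage comparisons are carried as data
  plumbing but have no dedicated recovery checks.
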
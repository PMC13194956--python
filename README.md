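# rezr

Quantification and statistical analysis of the **relative ellipsoid zone
reflectivity (rEZR)** on OCT B-scans — an imaging biomarker of
photoreceptor integrity studied across diabetic retinopathy (DR) stages.

## The problem and the statistic

On a cross-sectional OCT image, the outer retina shows two thin
hyperreflective bands: the **external limiting membrane (ELM)**, the
shallower band at the Müller-cell/photoreceptor junction, and the
**ellipsoid zone (EZ)**, the deeper band produced by the mitochondria-rich
photoreceptor inner segments.  Loss of EZ signal tracks photoreceptor
damage, but raw grey values depend on device brightness and media
opacity.  Normalising the EZ peak to the ELM peak — a non-neural band
with nearly constant signal across eccentricity — removes that nuisance:

```
rEZR = I_EZ / I_ELM
```

where `I_EZ` and `I_ELM` are the peak intensities (0–255 grey values) of
the two bands in the laterally averaged axial reflectivity profile of a
15 × 40 px region of interest (ROI).

The package implements the full measurement and analysis chain:

1. **ROI layout** — foveola; nasal/temporal (horizontal scans) and
   superior/inferior (vertical scans) positions at 500, 1000 and 2000 µm
   eccentricity; a peripapillary window 3000 µm nasal (horizontal scans
   only).  ROIs over vessel shadows or disrupted layers are shifted by at
   most 100 µm to the nearest clear position, else excluded.
2. **Profile → peaks → ratio** — lateral averaging, prominence-based
   two-peak detection (ELM = shallower, EZ = deeper), raw peak heights.
3. **ETDRS-style aggregation** — scan replicates are averaged per
   location; the central 1 mm disc / inner ring / outer ring pool the
   four directions at one eccentricity (mean over valid subareas),
   quadrants pool one direction across eccentricities (complete-case),
   and the total area is the unweighted mean of the three rings.
4. **Mixed models** — per-region linear mixed models of rEZR on DR group
   (noDR / NPDR / PDR) adjusted for age, disease duration, gender and eye
   side with a patient random intercept; a ring × group interaction model
   with an eye-within-patient intercept for the three scan replicates;
   and visual-acuity (logMAR) models.  Type III F-tests and contrast
   t-tests use Satterthwaite degrees of freedom; within-stage ring
   contrasts use Tukey adjustment.
5. **Synthetic ground truth** — a phantom generator renders B-scans with
   two Gaussian bands (controllable peaks, eccentricity-dependent EZ
   brightness, foveal pit, vessel shadows, noise) plus per-column truth,
   and a cohort simulator draws rEZR tables with the hierarchical
   structure the models assume — so every stage is testable end to end
   without any clinical data.

## Worked example

Measure a noisy phantom at every planned location:

```python
from rezr import PhantomSpec, generate_phantom, plan_rois, measure_scan

spec = PhantomSpec(noise_sd=5.0, seed=7)
scan, truth = generate_phantom(spec)
rois = plan_rois(scan)
for m, roi in zip(measure_scan(scan, rois), rois):
    t = truth.rezr[roi.columns].mean()
    print(f"{m.location.code:>14}  ELM {m.peaks.elm_intensity:6.1f}  "
          f"EZ {m.peaks.ez_intensity:6.1f}  rEZR {m.rezr:.3f}  (truth {t:.3f})")
```

```
       foveola  ELM  132.2  EZ  161.5  rEZR 1.222  (truth 1.219)
          n500  ELM  132.1  EZ  172.1  rEZR 1.302  (truth 1.286)
         n1000  ELM  139.9  EZ  188.9  rEZR 1.350  (truth 1.357)
         n2000  ELM  140.9  EZ  209.2  rEZR 1.485  (truth 1.497)
          t500  ELM  133.1  EZ  170.8  rEZR 1.283  (truth 1.286)
         t1000  ELM  139.3  EZ  187.9  rEZR 1.348  (truth 1.357)
         t2000  ELM  141.1  EZ  209.4  rEZR 1.484  (truth 1.497)
 peripapillary  ELM  141.0  EZ  209.7  rEZR 1.487  (truth 1.500)
```

The measured ratios recover the phantom truth to ~1% under noise
(SD 5 grey values), and the EZ brightening with eccentricity — lowest at
the foveola, highest perifoveally — is visible directly in the ratios.

Fit the group comparison on a simulated 64-eye / 44-patient cohort
(17 noDR, 33 NPDR, 14 PDR eyes; true contrasts −0.128 / −0.283):

```python
from rezr import CohortSimSpec, generate_cohort, fit_location_model, pairwise_group_contrasts

spec = CohortSimSpec(
    group_sizes=(17, 33, 14), n_patients=44,
    location_means={"outer_ring": 1.3},
    group_effects={"noDR": 0.0, "NPDR": -0.128, "PDR": -0.283},
    patient_sd=0.15, residual_sd=0.10, scans_per_eye=1, seed=5,
)
table, _ = generate_cohort(spec)
fit = fit_location_model(table.rename(columns={"rezr": "outer_ring"}), "outer_ring")
```

```
group F-test: F = 2.07 (df 2, 37.4), p = 0.140;  n = 64 (44)
  NPDR - noDR  -0.053 [-0.186; +0.080]  p = 0.422
  PDR - noDR   -0.166 [-0.336; +0.004]  p = 0.055
  PDR - NPDR   -0.113 [-0.252; +0.026]  p = 0.109
```

Estimates are adjusted-mean differences on the rEZR scale with
Satterthwaite 95% CIs; at this sample size a single draw of the cohort
estimates the true −0.283 contrast with an SE of ≈ 0.08, which is why the
reproduction script below averages over 200 simulated cohorts.

A `rezr` command exposes the same pipeline from the shell
(`rezr simulate | measure | aggregate | analyze | report`); every run
writes a manifest with the full configuration and seed.

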
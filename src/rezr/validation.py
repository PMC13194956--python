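"""Parameter-recovery and calibration simulations for the mixed models.

These routines exercise the full simulate → fit → test loop under known
truths: recovery of group contrasts at the study's sample size, recovery
of within-stage ring differences under the nested design, recovery of the
visual-acuity slope, type-I error of the group F-test under the null, and
empirical coverage of contrast confidence intervals.  They are used both
by the test suite and by the reproduction script.

Seeds: every replicate r uses ``base_seed + r`` so runs are reproducible
and embarrassingly parallel in structure (executed serially here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    fit_location_model,
    fit_ring_model,
    fit_va_model,
    pairwise_group_contrasts,
    ring_contrasts,
)
from .synthetic import CohortSimSpec, generate_cohort, generate_va_cohort

__all__ = [
    "recover_location_contrasts",
    "recover_ring_contrast",
    "recover_va_slope",
    "group_ftest_pvalues",
    "scaled_group_sizes",
]

STUDY_GROUP_SIZES = (17, 33, 14)  # eyes without DR / NPDR / PDR
STUDY_N_PATIENTS = 44


def scaled_group_sizes(n_patients: int, reference=STUDY_GROUP_SIZES, ref_patients=STUDY_N_PATIENTS):
    """Scale the study's eyes-per-group allocation to ``n_patients``.

    Total eyes keep the study's eyes-per-patient ratio; the split across
    groups follows largest-remainder proportional rounding.
    """
    from .synthetic import _largest_remainder

    total_eyes = int(round(n_patients * sum(reference) / ref_patients))
    return tuple(_largest_remainder(total_eyes, reference))


def recover_location_contrasts(
    truth_npdr: float,
    truth_pdr: float,
    n_seeds: int = 200,
    base_seed: int = 1,
    group_sizes=STUDY_GROUP_SIZES,
    n_patients: int = STUDY_N_PATIENTS,
    patient_sd: float = 0.15,
    residual_sd: float = 0.10,
    region: str = "outer_ring",
    base_mean: float = 1.3,
) -> pd.DataFrame:
    """Simulate cohorts with known group contrasts and refit them.

    Each replicate draws one eye-level cohort (one value per eye, patient
    random intercept, covariate effects zero) with the NPDR−noDR and
    PDR−noDR contrasts set to the supplied truths, fits the location
    model, and records the three pairwise contrast estimates with their
    CIs.  The mean of each estimate column is the recovery check; the CI
    columns support coverage checks.
    """
    rows = []
    for r in range(n_seeds):
        spec = CohortSimSpec(
            group_sizes=tuple(group_sizes),
            n_patients=n_patients,
            location_means={region: base_mean},
            group_effects={"noDR": 0.0, "NPDR": truth_npdr, "PDR": truth_pdr},
            patient_sd=patient_sd,
            eye_sd=0.0,
            residual_sd=residual_sd,
            scans_per_eye=1,
            seed=base_seed + r,
        )
        table, _ = generate_cohort(spec)
        wide = table.rename(columns={"rezr": region})
        fit = fit_location_model(wide, region)
        cons = {c.label: c for c in pairwise_group_contrasts(fit)}
        rows.append(
            {
                "seed": base_seed + r,
                "npdr_vs_nodr": cons["NPDR - noDR"].estimate,
                "pdr_vs_nodr": cons["PDR - noDR"].estimate,
                "pdr_vs_npdr": cons["PDR - NPDR"].estimate,
                "pdr_ci_low": cons["PDR - noDR"].ci_low,
                "pdr_ci_high": cons["PDR - noDR"].ci_high,
                "npdr_ci_low": cons["NPDR - noDR"].ci_low,
                "npdr_ci_high": cons["NPDR - noDR"].ci_high,
                "f_p": fit.ftests.loc["group", "p"],
            }
        )
    return pd.DataFrame(rows)


def recover_ring_contrast(
    ring_means_nodr=(1.0, 1.148, 1.278),
    group_central_outer={"NPDR": -0.110, "PDR": -0.173},
    group_inner_outer={"NPDR": -0.094, "PDR": -0.120},
    n_seeds: int = 200,
    base_seed: int = 1,
    group_sizes=STUDY_GROUP_SIZES,
    n_patients: int = STUDY_N_PATIENTS,
    patient_var: float = 0.02,
    eye_var: float = 0.0025,
    residual_var: float = 0.01,
    scans_per_eye: int = 3,
) -> pd.DataFrame:
    """Recover within-stage ring differences from the nested ring model.

    The no-DR ring means are given directly; the other stages keep the
    outer-ring value (shifted by a small overall group effect) and get
    their central/inner levels from their stated central−outer and
    inner−outer differences.  Each replicate simulates scan-level data
    (``scans_per_eye`` replicates per eye per ring; patient, eye-within-
    patient and residual variances as given), fits the ring model with
    interaction and nested random intercepts, and records the
    central−outer Tukey contrast estimate per stage.
    """
    central, inner, outer = ring_means_nodr
    location_means = {
        "central_1mm": central,
        "inner_ring": inner,
        "outer_ring": outer,
    }
    group_effects = {"noDR": 0.0, "NPDR": -0.05, "PDR": -0.15}
    gle = {}
    for g in ("NPDR", "PDR"):
        gle[(g, "central_1mm")] = (outer + group_central_outer[g]) - central
        gle[(g, "inner_ring")] = (outer + group_inner_outer[g]) - inner
    rows = []
    for r in range(n_seeds):
        spec = CohortSimSpec(
            group_sizes=tuple(group_sizes),
            n_patients=n_patients,
            location_means=location_means,
            group_effects=group_effects,
            group_location_effects=gle,
            patient_sd=float(np.sqrt(patient_var)),
            eye_sd=float(np.sqrt(eye_var)),
            residual_sd=float(np.sqrt(residual_var)),
            scans_per_eye=scans_per_eye,
            seed=base_seed + r,
        )
        table, _ = generate_cohort(spec)
        fit = fit_ring_model(table.rename(columns={"region": "ring"}))
        cons = {c.label: c for c in ring_contrasts(fit)}
        row = {"seed": base_seed + r, "interaction_p": fit.ftests.loc["ring:group", "p"]}
        for g in ("noDR", "NPDR", "PDR"):
            con = cons[f"central_1mm - outer_ring ({g})"]
            row[f"central_outer_{g}"] = con.estimate
            row[f"central_outer_{g}_p"] = con.p
        rows.append(row)
    return pd.DataFrame(rows)


def recover_va_slope(
    truth_slope: float = -0.171,
    n_seeds: int = 200,
    base_seed: int = 1,
    group_sizes=STUDY_GROUP_SIZES,
    n_patients: int = STUDY_N_PATIENTS,
    patient_sd: float = 0.05,
    residual_sd: float = 0.08,
    rezr_sd: float = 0.2,
) -> pd.DataFrame:
    """Recover the univariable VA-on-rEZR slope from the VA mixed model."""
    rows = []
    for r in range(n_seeds):
        eyes, _ = generate_va_cohort(
            slope=truth_slope,
            group_sizes=tuple(group_sizes),
            n_patients=n_patients,
            patient_sd=patient_sd,
            residual_sd=residual_sd,
            rezr_sd=rezr_sd,
            seed=base_seed + r,
        )
        fit = fit_va_model(eyes, predictor="total")
        row = fit.params.loc["rezr_total"]
        rows.append(
            {
                "seed": base_seed + r,
                "slope": float(row["estimate"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p": float(row["p"]),
            }
        )
    return pd.DataFrame(rows)


def group_ftest_pvalues(
    n_reps: int = 1000,
    n_patients: int = 500,
    base_seed: int = 1,
    patient_sd: float = 0.15,
    residual_sd: float = 0.10,
    region: str = "outer_ring",
) -> np.ndarray:
    """Group F-test p-values under the null (no group effect).

    The cohort keeps the study's eyes-per-patient ratio and group split,
    scaled to ``n_patients``.  Under a well-calibrated test the returned
    p-values are uniform, so the rejection rate at 0.05 estimates the
    type-I error.
    """
    sizes = scaled_group_sizes(n_patients)
    ps = np.empty(n_reps)
    for r in range(n_reps):
        spec = CohortSimSpec(
            group_sizes=sizes,
            n_patients=n_patients,
            location_means={region: 1.3},
            group_effects={"noDR": 0.0, "NPDR": 0.0, "PDR": 0.0},
            patient_sd=patient_sd,
            eye_sd=0.0,
            residual_sd=residual_sd,
            scans_per_eye=1,
            seed=base_seed + r,
        )
        table, _ = generate_cohort(spec)
        fit = fit_location_model(table.rename(columns={"rezr": region}), region)
        ps[r] = float(fit.ftests.loc["group", "p"])
    return ps
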
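"""Shared fixtures: phantoms and small cohorts, generated at test time."""

import numpy as np
import pytest

from rezr.synthetic import CohortSimSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, shadow-free horizontal phantom with its ground truth."""
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    scan, truth = generate_phantom(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def vertical_phantom():
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    scan, truth = generate_phantom(spec, orientation="vertical")
    return spec, scan, truth


@pytest.fixture(scope="session")
def study_cohort():
    """Eye-level cohort at the study's size with known group contrasts."""
    spec = CohortSimSpec(
        group_sizes=(17, 33, 14),
        n_patients=44,
        location_means={"outer_ring": 1.3},
        group_effects={"noDR": 0.0, "NPDR": -0.128, "PDR": -0.283},
        patient_sd=0.15,
        eye_sd=0.0,
        residual_sd=0.10,
        scans_per_eye=1,
        seed=5,
    )
    table, truth = generate_cohort(spec)
    return table, truth
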
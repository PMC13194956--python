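"""Synthetic OCT phantoms and simulated cohorts with known ground truth.

Two generators make every downstream stage of the pipeline testable
without any real data:

* :func:`generate_phantom` renders a B-scan whose every A-scan (column)
  contains two Gaussian hyperreflective bands over a uniform background —
  the shallower band standing in for the external limiting membrane (ELM),
  the deeper one for the photoreceptor ellipsoid zone (EZ) — with optional
  eccentricity-dependent EZ brightness, vessel shadows and additive
  Gaussian noise.  The returned :class:`PhantomTruth` records, per column,
  the true band depths, the true peak grey values and the true rEZR.

* :func:`generate_cohort` draws per-scan rEZR observations with the
  hierarchical structure the statistical models assume: a patient random
  intercept, an eye-within-patient random intercept, a per-measurement
  residual, group (DR-stage) effects, region means and linear covariate
  effects.

Every stochastic operation takes an explicit integer seed; there is no
global RNG state, and identical specs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BScan, NPDR_SUBSTAGES, STAGES

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "CohortSimSpec",
    "generate_cohort",
    "generate_va_cohort",
    "generate_eligibility_roster",
    "foveal_pit_profile",
    "flat_depth_profile",
    "eccentricity_ramp",
    "constant_peak",
]


# ---------------------------------------------------------------------------
# named profile factories (so specs round-trip through YAML)
# ---------------------------------------------------------------------------

def flat_depth_profile(base_um: float = 600.0) -> Callable[[np.ndarray], np.ndarray]:
    """ELM depth independent of eccentricity."""

    def depth(ecc_um: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(ecc_um, dtype=float), base_um)

    return depth


def foveal_pit_profile(
    base_um: float = 600.0, dip_um: float = 120.0, pit_radius_um: float = 500.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Outer bands drawn shallower towards the foveal centre.

    The elevation follows a raised-cosine (cos²) bump over the central
    ``±pit_radius_um``: full ``dip_um`` at the foveola, zero at the rim,
    with zero slope at both — so measurement windows at the foveola and at
    the rim eccentricity sit on locally flat band geometry.
    """

    def depth(ecc_um: np.ndarray) -> np.ndarray:
        ecc = np.asarray(ecc_um, dtype=float)
        inside = np.abs(ecc) < pit_radius_um
        bump = np.zeros_like(ecc)
        bump[inside] = dip_um * np.cos(np.pi * ecc[inside] / (2.0 * pit_radius_um)) ** 2
        return base_um - bump

    return depth


def constant_peak(value: float = 180.0) -> Callable[[np.ndarray], np.ndarray]:
    """EZ peak amplitude independent of eccentricity."""

    def peak(ecc_um: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(ecc_um, dtype=float), value)

    return peak


def eccentricity_ramp(
    center: float = 150.0, gain_per_um: float = 0.02, max_ecc_um: float = 2000.0
) -> Callable[[np.ndarray], np.ndarray]:
    """EZ brightness rising linearly with eccentricity, then saturating.

    Emulates the perifoveal EZ reflectivity maximum: amplitude
    ``center + gain_per_um * min(|ecc|, max_ecc_um)``.
    """

    def peak(ecc_um: np.ndarray) -> np.ndarray:
        ecc = np.abs(np.asarray(ecc_um, dtype=float))
        return center + gain_per_um * np.minimum(ecc, max_ecc_um)

    return peak


_PROFILE_REGISTRY: dict[str, Callable[..., Callable]] = {
    "flat": flat_depth_profile,
    "foveal_pit": foveal_pit_profile,
    "constant": constant_peak,
    "eccentricity_ramp": eccentricity_ramp,
}


def _resolve_profile(profile) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a callable, a registry name, or a (name, kwargs) pair."""
    if callable(profile):
        return profile
    if isinstance(profile, str):
        return _PROFILE_REGISTRY[profile]()
    name, kwargs = profile
    return _PROFILE_REGISTRY[name](**dict(kwargs))


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the two-band B-scan phantom.

    Shadows are given as ``(start_um, end_um, attenuation)`` intervals in
    signed µm of eccentricity relative to the foveola (negative values lie
    on the lower-column side); the whole A-scan inside the interval is
    multiplied by the attenuation factor, as a vessel shadow attenuates
    signal at all depths beneath it.
    """

    image_height_px: int = 320
    image_width_px: int = 1024
    axial_scale: float = 3.0  # µm / px
    lateral_scale: float = 10.0  # µm / px
    fovea_col: int = 512
    elm_depth_profile: object = ("foveal_pit", {"base_um": 600.0, "dip_um": 120.0})
    band_gap_um: float = 30.0  # ELM-to-EZ centre distance
    elm_peak: float = 120.0  # grey value above background
    ez_peak_profile: object = ("eccentricity_ramp", {"center": 150.0})
    band_sigma_um: float = 6.0  # Gaussian axial band width
    background: float = 20.0
    shadow_columns: list = field(default_factory=list)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background <= 255.0:
            raise ValueError("background must lie in [0, 255]")
        if not 0.0 < self.elm_peak <= 255.0:
            raise ValueError("elm_peak must lie in (0, 255]")
        if self.band_gap_um <= 3.0 * self.band_sigma_um:
            raise ValueError(
                "band_gap_um must exceed 3 * band_sigma_um so the two peaks "
                f"are resolvable (gap {self.band_gap_um} µm, sigma "
                f"{self.band_sigma_um} µm)"
            )
        for start, end, att in self.shadow_columns:
            if not 0.0 < att <= 1.0:
                raise ValueError(f"shadow attenuation must lie in (0, 1], got {att}")
            if end <= start:
                raise ValueError("shadow interval must have end_um > start_um")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Per-column ground truth for one phantom B-scan.

    Peak values are read off the pixel-sampled noiseless image (shadow
    attenuation applied, before noise and 8-bit quantisation), i.e. they
    include the background pedestal exactly as a profile reader would see
    it, and ``rezr = ez_peak / elm_peak`` per column.
    """

    elm_depth_um: np.ndarray
    ez_depth_um: np.ndarray
    elm_row: np.ndarray
    ez_row: np.ndarray
    elm_peak: np.ndarray
    ez_peak: np.ndarray
    rezr: np.ndarray
    shadow_mask: np.ndarray  # True where a shadow attenuates the column
    shadow_factor: np.ndarray

    @property
    def validity_mask(self) -> np.ndarray:
        """Columns with continuous (unshadowed) layers."""
        return ~self.shadow_mask

    def band_centre_row(self, columns: Sequence[int]) -> int:
        """Mean mid-band row over ``columns`` — the axial placement hint."""
        cols = np.asarray(columns)
        return int(round(float((self.elm_row[cols] + self.ez_row[cols]).mean() / 2.0)))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{
            k: np.asarray(v, dtype=bool if k == "shadow_mask" else float)
            for k, v in payload.items()
        })


def generate_phantom(
    spec: PhantomSpec,
    orientation: str = "horizontal",
    eye_side: str = "right",
    scan_index: int = 1,
    quantize: bool = True,
) -> tuple[BScan, PhantomTruth]:
    """Render a two-band phantom B-scan and its ground truth.

    With ``quantize=False`` the returned scan carries the float image
    before 8-bit rounding (noise, if any, still applied) — the path used
    to test brightness invariance of the rEZR ratio pre-quantisation.
    """
    h, w = spec.image_height_px, spec.image_width_px
    cols = np.arange(w)
    ecc_um = (cols - spec.fovea_col) * spec.lateral_scale  # signed

    elm_depth = np.asarray(_resolve_profile(spec.elm_depth_profile)(ecc_um), dtype=float)
    ez_depth = elm_depth + spec.band_gap_um
    ez_amp = np.asarray(_resolve_profile(spec.ez_peak_profile)(np.abs(ecc_um)), dtype=float)
    if np.any(ez_amp + spec.background > 255.0 + 1e-9) or np.any(
        spec.elm_peak + spec.background > 255.0 + 1e-9
    ):
        raise ValueError("band peak plus background exceeds the 8-bit grey range")

    margin = 3.0 * spec.band_sigma_um
    depth_extent = h * spec.axial_scale
    bad = (elm_depth - margin < 0) | (ez_depth + margin > depth_extent)
    if np.any(bad):
        col = int(np.argmax(bad))
        raise ValueError(
            "band placement outside image extent at lateral position "
            f"{ecc_um[col]:+.0f} µm (column {col}): ELM {elm_depth[col]:.0f} µm, "
            f"EZ {ez_depth[col]:.0f} µm, image depth {depth_extent:.0f} µm"
        )

    z = np.arange(h)[:, None] * spec.axial_scale  # row-centre depths, µm
    two_s2 = 2.0 * spec.band_sigma_um**2
    signal = (
        spec.background
        + spec.elm_peak * np.exp(-((z - elm_depth[None, :]) ** 2) / two_s2)
        + ez_amp[None, :] * np.exp(-((z - ez_depth[None, :]) ** 2) / two_s2)
    )

    factor = np.ones(w)
    for start, end, att in spec.shadow_columns:
        inside = (ecc_um >= start) & (ecc_um <= end)
        factor[inside] *= att
    noiseless = signal * factor[None, :]

    img = noiseless
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = noiseless + rng.normal(0.0, spec.noise_sd, size=noiseless.shape)
    if quantize:
        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    else:
        pixels = np.clip(img, 0.0, 255.0)

    # truth peaks: maximum of the sampled noiseless profile in a half-gap
    # window around each band centre
    half = max(1, int(round(spec.band_gap_um / 2.0 / spec.axial_scale)))
    elm_row0 = np.rint(elm_depth / spec.axial_scale).astype(int)
    ez_row0 = np.rint(ez_depth / spec.axial_scale).astype(int)
    offsets = np.arange(-half, half + 1)

    def _peak_rows(row0: np.ndarray) -> np.ndarray:
        idx = np.clip(row0[None, :] + offsets[:, None], 0, h - 1)
        vals = noiseless[idx, cols[None, :]]
        return idx[np.argmax(vals, axis=0), cols]

    elm_row = _peak_rows(elm_row0)
    ez_row = _peak_rows(ez_row0)
    elm_peak = noiseless[elm_row, cols]
    ez_peak = noiseless[ez_row, cols]

    truth = PhantomTruth(
        elm_depth_um=elm_depth,
        ez_depth_um=ez_depth,
        elm_row=elm_row.astype(float),
        ez_row=ez_row.astype(float),
        elm_peak=elm_peak,
        ez_peak=ez_peak,
        rezr=ez_peak / elm_peak,
        shadow_mask=factor < 1.0,
        shadow_factor=factor,
    )
    scan = BScan(
        pixels=pixels,
        axial_scale=spec.axial_scale,
        lateral_scale=spec.lateral_scale,
        fovea_col=spec.fovea_col,
        orientation=orientation,
        eye_side=eye_side,
        scan_index=scan_index,
    )
    return scan, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Generative model for a simulated rEZR cohort.

    One response row per scan × eye × region::

        rezr = location_mean[region] + group_effect[stage]
             + group_location_effect[(stage, region)]
             + age_effect * (age - age_mean) + duration_effect * (dur - dur_mean)
             + gender_effect * 1[female] + eye_side_effect * 1[left]
             + b_patient + b_eye + residual

    ``group_sizes`` are eyes per analysis group (noDR, NPDR, PDR); both
    eyes of a two-eye patient share the group.  With ``n_patients`` given,
    the number of two-eye patients is ``total_eyes - n_patients`` and they
    are allocated to groups by deterministic largest-remainder rounding;
    otherwise two-eye patients are drawn with ``two_eye_probability``.
    """

    group_sizes: tuple[int, int, int] = (17, 33, 14)
    n_patients: int | None = 44
    two_eye_probability: float = 0.45
    location_means: Mapping[str, float] = field(
        default_factory=lambda: {"outer_ring": 1.3}
    )
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: {"noDR": 0.0, "NPDR": 0.0, "PDR": 0.0}
    )
    group_location_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    age_effect: float = 0.0
    duration_effect: float = 0.0
    gender_effect: float = 0.0
    eye_side_effect: float = 0.0
    patient_sd: float = 0.15
    eye_sd: float = 0.0
    residual_sd: float = 0.10
    scans_per_eye: int = 3
    age_mean: float = 62.0
    age_sd: float = 9.0
    duration_mean: float = 15.0
    duration_sd: float = 8.0
    female_rate: float = 0.27
    duration_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(STAGES):
            raise ValueError("group_sizes must give eyes for noDR, NPDR, PDR")
        if any(g < 0 for g in self.group_sizes):
            raise ValueError("group_sizes must be non-negative")
        for name in ("patient_sd", "eye_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scans_per_eye < 1:
            raise ValueError("scans_per_eye must be at least 1")
        total = sum(self.group_sizes)
        if self.n_patients is not None:
            n_two = total - self.n_patients
            if not 0 <= n_two <= self.n_patients:
                raise ValueError(
                    f"{self.n_patients} patients cannot supply {total} eyes with "
                    "at most two eyes per patient"
                )


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        out = [0] * len(weights)
        out[0] = total
        return out
    exact = total * weights / weights.sum()
    alloc = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - alloc)):
        if alloc.sum() >= total:
            break
        alloc[i] += 1
    return alloc.tolist()


def _allocate_patients(spec: CohortSimSpec, rng: np.random.Generator):
    """Yield (stage, n_eyes) per patient honouring the group eye counts."""
    sizes = list(spec.group_sizes)
    if spec.n_patients is not None:
        n_two = sum(sizes) - spec.n_patients
        two = _largest_remainder(n_two, sizes)
        # respect the per-group ceiling floor(eyes/2), shifting surplus
        for i in range(len(sizes)):
            cap = sizes[i] // 2
            if two[i] > cap:
                surplus = two[i] - cap
                two[i] = cap
                for j in np.argsort(sizes)[::-1]:
                    room = sizes[j] // 2 - two[j]
                    take = min(room, surplus)
                    two[j] += take
                    surplus -= take
                if surplus:
                    raise ValueError("group sizes incompatible with patient count")
    else:
        two = []
        for size in sizes:
            n2 = int(rng.binomial(size // 2, spec.two_eye_probability))
            two.append(n2)
    plan = []
    for stage, size, n2 in zip(STAGES, sizes, two):
        plan.extend((stage, 2) for _ in range(n2))
        plan.extend((stage, 1) for _ in range(size - 2 * n2))
    return plan


def generate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a long rEZR table and return it with the truth record.

    Returns a frame with one row per scan × eye × region (columns
    ``patient_id, eye_id, eye_side, dr_stage, region, scan_index, rezr,
    age, duration, gender``) and a dict echoing every true parameter.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _allocate_patients(spec, rng)
    regions = list(spec.location_means)

    rows = []
    eye_counter = 0
    for pid, (stage, n_eyes) in enumerate(plan):
        age = rng.normal(spec.age_mean, spec.age_sd)
        duration = max(0.0, rng.normal(spec.duration_mean, spec.duration_sd))
        female = rng.random() < spec.female_rate
        b_patient = rng.normal(0.0, spec.patient_sd) if spec.patient_sd else 0.0
        if n_eyes == 2:
            sides = ["right", "left"]
        else:
            sides = ["right" if rng.random() < 0.5 else "left"]
        for side in sides:
            b_eye = rng.normal(0.0, spec.eye_sd) if spec.eye_sd else 0.0
            eye_id = f"E{eye_counter:04d}"
            eye_counter += 1
            for scan in range(1, spec.scans_per_eye + 1):
                for region in regions:
                    mean = (
                        spec.location_means[region]
                        + spec.group_effects.get(stage, 0.0)
                        + dict(spec.group_location_effects).get((stage, region), 0.0)
                        + spec.age_effect * (age - spec.age_mean)
                        + spec.duration_effect * (duration - spec.duration_mean)
                        + spec.gender_effect * float(female)
                        + spec.eye_side_effect * float(side == "left")
                    )
                    eps = rng.normal(0.0, spec.residual_sd) if spec.residual_sd else 0.0
                    rows.append(
                        {
                            "patient_id": f"P{pid:04d}",
                            "eye_id": eye_id,
                            "eye_side": side,
                            "dr_stage": stage,
                            "region": region,
                            "scan_index": scan,
                            "rezr": mean + b_patient + b_eye + eps,
                            "age": age,
                            "duration": duration,
                            "gender": "female" if female else "male",
                        }
                    )
    table = pd.DataFrame(rows)
    if spec.duration_missing_rate > 0:
        by_patient = table["patient_id"].unique()
        miss = by_patient[
            rng.random(len(by_patient)) < spec.duration_missing_rate
        ]
        table.loc[table["patient_id"].isin(miss), "duration"] = np.nan
    truth = {
        "group_effects": dict(spec.group_effects),
        "location_means": dict(spec.location_means),
        "group_location_effects": {
            f"{g}:{r}": v for (g, r), v in dict(spec.group_location_effects).items()
        },
        "patient_sd": spec.patient_sd,
        "eye_sd": spec.eye_sd,
        "residual_sd": spec.residual_sd,
        "n_eyes": int(table["eye_id"].nunique()),
        "n_patients": int(table["patient_id"].nunique()),
        "seed": spec.seed,
    }
    return table, truth


def generate_va_cohort(
    slope: float = -0.171,
    group_sizes: tuple[int, int, int] = (17, 33, 14),
    n_patients: int | None = 44,
    rezr_mean: float = 1.2,
    rezr_sd: float = 0.2,
    patient_sd: float = 0.05,
    residual_sd: float = 0.08,
    intercept: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-eye visual acuity driven linearly by total-area rEZR.

    ``logmar = intercept + slope * rezr + b_patient + residual`` with one
    row per eye; the default intercept centres logMAR at zero.
    """
    if intercept is None:
        intercept = -slope * rezr_mean
    spec = CohortSimSpec(
        group_sizes=group_sizes,
        n_patients=n_patients,
        location_means={"total": rezr_mean},
        patient_sd=0.0,
        eye_sd=0.0,
        residual_sd=rezr_sd,
        scans_per_eye=1,
        seed=seed,
    )
    eyes, _ = generate_cohort(spec)
    eyes = eyes.rename(columns={"rezr": "rezr_total"}).drop(
        columns=["region", "scan_index"]
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7041]))
    b_p = {
        pid: rng.normal(0.0, patient_sd) for pid in eyes["patient_id"].unique()
    }
    eyes["bcva_logmar"] = (
        intercept
        + slope * eyes["rezr_total"]
        + eyes["patient_id"].map(b_p)
        + rng.normal(0.0, residual_sd, size=len(eyes))
    )
    truth = {
        "slope": slope,
        "intercept": intercept,
        "patient_sd": patient_sd,
        "residual_sd": residual_sd,
        "n_eyes": int(len(eyes)),
        "n_patients": int(eyes["patient_id"].nunique()),
    }
    return eyes, truth


# ---------------------------------------------------------------------------
# eligibility roster
# ---------------------------------------------------------------------------

def generate_eligibility_roster(
    counts: Mapping[str, int],
    n_patients: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a per-eye roster with screening flags matching exact counts.

    ``counts`` must give ``recruited`` and may give exclusion counts
    (``low_quality``, ``dme``, ``quiescent_pdr`` — assigned to disjoint
    eyes) and DR-stage counts for the remaining eligible eyes (keys among
    ``noDR``, ``mild``, ``moderate``, ``severe``, ``NPDR``, ``PDR``).
    Eligible eyes without an explicit stage default to ``noDR``.
    """
    counts = dict(counts)
    recruited = int(counts.pop("recruited"))
    if recruited < 0:
        raise ValueError("recruited must be non-negative")
    flag_names = ("low_quality", "dme", "quiescent_pdr")
    flag_counts = {f: int(counts.pop(f, 0)) for f in flag_names}
    if any(v < 0 for v in flag_counts.values()):
        raise ValueError("exclusion counts must be non-negative")
    n_excluded = sum(flag_counts.values())
    if n_excluded > recruited:
        raise ValueError("more excluded eyes than recruited")

    stage_keys = [k for k in ("noDR", "mild", "moderate", "severe", "NPDR", "PDR") if k in counts]
    stage_counts = {k: int(counts.pop(k)) for k in stage_keys}
    if counts:
        raise ValueError(f"unknown roster count key(s): {sorted(counts)}")
    n_eligible = recruited - n_excluded
    if sum(stage_counts.values()) > n_eligible:
        raise ValueError("stage counts exceed the number of eligible eyes")

    rng = np.random.default_rng(seed)
    rows = []
    stages = []
    for k, v in stage_counts.items():
        stages.extend([k] * v)
    stages.extend(["noDR"] * (n_eligible - len(stages)))

    if n_patients is None:
        n_patients = recruited - recruited // 3  # ~1/3 of patients contribute 2 eyes
    n_two = max(0, min(recruited - n_patients, n_patients))
    patient_of_eye = []
    pid = 0
    for _ in range(n_two):
        patient_of_eye.extend([pid, pid])
        pid += 1
    while len(patient_of_eye) < recruited:
        patient_of_eye.append(pid)
        pid += 1

    flags_per_eye = (
        [("low_quality",)] * flag_counts["low_quality"]
        + [("dme",)] * flag_counts["dme"]
        + [("quiescent_pdr",)] * flag_counts["quiescent_pdr"]
        + [()] * n_eligible
    )
    stage_iter = iter(stages)
    for i in range(recruited):
        flags = flags_per_eye[i]
        excluded = bool(flags)
        stage = "PDR" if "quiescent_pdr" in flags else (
            "noDR" if excluded else next(stage_iter)
        )
        rows.append(
            {
                "eye_id": f"E{i:04d}",
                "patient_id": f"P{patient_of_eye[i]:04d}",
                "eye_side": "right" if i % 2 == 0 else "left",
                "dr_stage": stage,
                "low_quality": "low_quality" in flags,
                "dme": "dme" in flags,
                "quiescent_pdr": "quiescent_pdr" in flags,
                # eligible eyes must not trip the thresholds by chance
                "q_score": 20.0 if "low_quality" in flags else float(
                    np.round(np.clip(rng.normal(33.0, 4.0), 26.0, None), 1)
                ),
                "cst_um": 300.0 if "dme" in flags else float(
                    np.round(np.clip(rng.normal(220.0, 15.0), None, 248.0), 1)
                ),
                "age": float(np.round(rng.normal(62.0, 9.0), 1)),
                "duration": float(np.round(max(0.0, rng.normal(15.0, 8.0)), 1)),
                "gender": "female" if rng.random() < 0.27 else "male",
                "bcva_logmar": float(np.round(rng.normal(0.02, 0.1), 2)),
            }
        )
    return pd.DataFrame(rows)
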
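"""Combination of per-scan subarea measurements into analysis regions.

The spatial layout mirrors the ETDRS grid with point subareas: the
central 1 mm disc pools the four 500 µm subareas, the inner ring the four
at 1000 µm, the outer ring the four at 2000 µm; quadrants pool one
direction across the three eccentricities; the total area is the mean of
the three ring values.  The missingness rules differ deliberately:

* within a **ring**, subarea values are assumed similar, so the mean is
  taken over all valid observations (missing only if all four are);
* within a **quadrant**, values differ with eccentricity, so the mean is
  complete-case — any missing subarea makes the quadrant missing;
* the **total** is the unweighted mean of the three ring values and
  requires all three rings (each ring may itself rest on partial data).

Scan replicates are averaged first (mean over the ok-status replicates of
each location), then subareas are combined into regions.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "combine_scans",
    "ring_mean",
    "quadrant_mean",
    "total_area",
    "build_eye_table",
    "build_ring_long",
    "RING_ECCENTRICITY_UM",
    "REGION_COLUMNS",
]

RING_ECCENTRICITY_UM = {"central_1mm": 500, "inner_ring": 1000, "outer_ring": 2000}
_QUADRANTS = {"nasal": "n", "temporal": "t", "superior": "s", "inferior": "i"}

REGION_COLUMNS = (
    "foveola",
    "central_1mm",
    "inner_ring",
    "outer_ring",
    "total",
    "peripapillary",
    "quadrant_nasal",
    "quadrant_temporal",
    "quadrant_superior",
    "quadrant_inferior",
)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def ring_mean(subareas: Sequence[float]) -> float:
    """Mean over valid subarea values; NaN only if all are missing."""
    vals = [v for v in subareas if not _is_missing(v)]
    return float(np.mean(vals)) if vals else float("nan")


def quadrant_mean(subareas: Sequence[float]) -> float:
    """Complete-case mean: NaN if any of the subarea values is missing."""
    if any(_is_missing(v) for v in subareas):
        return float("nan")
    return float(np.mean(list(subareas)))


def total_area(central: float, inner: float, outer: float) -> float:
    """Unweighted mean of the three ring values; NaN if any ring is."""
    if any(_is_missing(v) for v in (central, inner, outer)):
        return float("nan")
    return float(np.mean([central, inner, outer]))


def combine_scans(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average scan replicates per eye and location.

    Expects a long measurement table with at least ``eye_id``,
    ``location``, ``scan_index``, ``rezr`` and ``status`` columns (as
    produced by :func:`rezr.reflectivity.measurements_to_frame`).  For
    each eye × location, returns the mean rEZR over replicates with
    status ``ok``; the location is missing (NaN) when no replicate is ok.
    Identifier columns (``patient_id`` etc.) are carried through.
    """
    ok = measurements[measurements["status"] == "ok"]
    keys = ["eye_id", "location"]
    carried = [
        c
        for c in ("patient_id", "eye_side")
        if c in measurements.columns
    ]
    means = ok.groupby(keys)["rezr"].mean()
    # keep every eye × location that was attempted, missing where no ok rep
    attempted = measurements[keys + carried].drop_duplicates(subset=keys)
    out = attempted.merge(means.rename("rezr"), on=keys, how="left")
    return out.reset_index(drop=True)


def _subarea(series: pd.Series, code: str) -> float:
    return float(series[code]) if code in series.index else float("nan")


def build_eye_table(
    subareas: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Wide per-eye table of region rEZR values, optionally with covariates.

    ``subareas`` is the output of :func:`combine_scans`.  Region columns
    follow the ring / quadrant / total rules above.  When a roster is
    given, its covariate columns are merged on ``eye_id``.
    """
    rows = []
    for eye_id, grp in subareas.groupby("eye_id", sort=True):
        series = grp.set_index("location")["rezr"]
        row: dict = {"eye_id": eye_id}
        for c in ("patient_id", "eye_side"):
            if c in grp.columns:
                row[c] = grp[c].iloc[0]
        row["foveola"] = _subarea(series, "foveola")
        row["peripapillary"] = _subarea(series, "peripapillary")
        rings = {}
        for ring, ecc in RING_ECCENTRICITY_UM.items():
            rings[ring] = ring_mean(
                [_subarea(series, f"{a}{ecc}") for a in _QUADRANTS.values()]
            )
            row[ring] = rings[ring]
        row["total"] = total_area(
            rings["central_1mm"], rings["inner_ring"], rings["outer_ring"]
        )
        for direction, abbrev in _QUADRANTS.items():
            row[f"quadrant_{direction}"] = quadrant_mean(
                [
                    _subarea(series, f"{abbrev}{ecc}")
                    for ecc in RING_ECCENTRICITY_UM.values()
                ]
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if roster is not None:
        cov = roster.drop(
            columns=[c for c in roster.columns if c in table.columns and c != "eye_id"]
        )
        table = table.merge(cov, on="eye_id", how="left")
        for c in ("patient_id", "eye_side"):
            if c not in table.columns and c in roster.columns:
                table[c] = table["eye_id"].map(roster.set_index("eye_id")[c])
    return table


def build_ring_long(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-scan ring values for the ring mixed model (3 rows per eye/ring).

    For each eye × scan replicate × ring, the ring value is the mean over
    the valid subarea measurements of that replicate (the same
    partial-data tolerance as the per-eye ring mean).  Horizontal and
    vertical scans with the same ``scan_index`` contribute their
    respective direction pairs to one replicate.
    """
    rows = []
    carried = [c for c in ("patient_id", "eye_side") if c in measurements.columns]
    for (eye_id, scan_index), grp in measurements.groupby(["eye_id", "scan_index"]):
        ok = grp[grp["status"] == "ok"].set_index("location")["rezr"]
        for ring, ecc in RING_ECCENTRICITY_UM.items():
            value = ring_mean(
                [_subarea(ok, f"{a}{ecc}") for a in _QUADRANTS.values()]
            )
            row = {
                "eye_id": eye_id,
                "scan_index": scan_index,
                "ring": ring,
                "rezr": value,
            }
            for c in carried:
                row[c] = grp[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)
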
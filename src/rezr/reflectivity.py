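"""Axial reflectivity profiles, band-peak detection and the rEZR ratio.

The measurement replicates a plot-profile reading: average the window's
pixels laterally to get one mean grey value per row (an axial profile),
find the two hyperreflective outer-retinal peaks, take the raw profile
value at each peak, and form

    rEZR = EZ peak intensity / ELM peak intensity,

the ratio of the deeper (ellipsoid zone) to the shallower (external
limiting membrane) band.  Normalising to the ELM — a band whose signal is
relatively constant across eccentricity — cancels global OCT brightness
variation, which is the reason the statistic is a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .io import BScan
from .roi import Location, ROISpec

__all__ = [
    "AxialProfile",
    "BandPeaks",
    "REZRMeasurement",
    "extract_axial_profile",
    "detect_band_peaks",
    "compute_rezr",
    "measure_scan",
    "measurements_to_frame",
]


@dataclass
class AxialProfile:
    """Mean grey value per ROI row, with the axial pixel pitch in µm."""

    values: np.ndarray
    axial_scale: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile must be one-dimensional")

    @property
    def row_depths(self) -> np.ndarray:
        """Depth of each row in µm from the ROI top."""
        return np.arange(len(self.values)) * self.axial_scale


@dataclass
class BandPeaks:
    """The two outer-retinal peaks: ELM (shallower) and EZ (deeper)."""

    elm_intensity: float
    elm_row: int
    ez_intensity: float
    ez_row: int

    def __post_init__(self) -> None:
        if not self.elm_row < self.ez_row:
            raise ValueError("ELM must be the shallower band (elm_row < ez_row)")
        if self.elm_intensity <= 0 or self.ez_intensity <= 0:
            raise ValueError("band peak intensities must be positive")


@dataclass
class REZRMeasurement:
    """Result of one ROI measurement on one scan."""

    location: Location
    scan_index: int
    rezr: float  # NaN unless status == "ok"
    peaks: BandPeaks | None
    status: str  # ok | excluded | peak_failure
    shift_um: float = 0.0
    n_peaks_found: int | None = None


def extract_axial_profile(
    scan: BScan | np.ndarray, roi: ROISpec, axial_scale: float | None = None
) -> AxialProfile:
    """Laterally average the ROI to one mean grey value per row.

    Accepts either a :class:`BScan` or a bare 2-D array (then
    ``axial_scale`` must be given — the float/pre-quantisation path).
    Excluded ROIs are a pipeline error, not a silent skip.
    """
    if roi.status == "excluded":
        raise ValueError(
            f"cannot profile an excluded ROI ({roi.location.code}: {roi.reason})"
        )
    if isinstance(scan, BScan):
        pixels, scale = scan.pixels, scan.axial_scale
    else:
        if axial_scale is None:
            raise ValueError("axial_scale is required when passing a bare array")
        pixels, scale = np.asarray(scan), float(axial_scale)
    window = pixels[roi.row_slice, roi.col_slice]
    if window.shape != (roi.height_px, roi.width_px):
        raise ValueError(
            f"ROI {roi.location.code} extends outside the image "
            f"(window shape {window.shape})"
        )
    return AxialProfile(values=window.mean(axis=1, dtype=float), axial_scale=scale)


def detect_band_peaks(
    profile: AxialProfile,
    min_prominence: float = 5.0,
    min_separation_um: float = 10.0,
    smooth_rows: int = 0,
) -> tuple[BandPeaks | None, int]:
    """Find the ELM and EZ peaks in an axial profile.

    Candidate peaks are local maxima with prominence of at least
    ``min_prominence`` grey values.  Among candidate pairs separated by at
    least ``min_separation_um``, the pair with the largest summed
    prominence wins (ties resolved towards the shallower pair); the
    shallower member is the ELM, the deeper the EZ, and intensities are
    the raw profile values at the peak rows.  Returns ``(peaks,
    n_candidates)`` with ``peaks=None`` when no qualifying pair exists —
    a recoverable ``peak_failure``, not an exception.

    ``smooth_rows`` (off by default) applies a moving average of that
    width before peak finding — profile readings are assumed to come
    from raw plot profiles, so smoothing is opt-in and the intensities
    are then read from the smoothed curve.
    """
    v = profile.values
    if smooth_rows and smooth_rows > 1:
        from scipy.ndimage import uniform_filter1d

        v = uniform_filter1d(v, size=int(smooth_rows))
    if len(v) < 5:
        raise ValueError("profile too short for peak detection (need >= 5 rows)")
    idx, props = find_peaks(v, prominence=min_prominence)
    n = len(idx)
    if n < 2:
        return None, n
    prom = props["prominences"]
    best = None
    best_key = None
    for a in range(n):
        for b in range(a + 1, n):
            if (idx[b] - idx[a]) * profile.axial_scale < min_separation_um:
                continue
            key = (-(prom[a] + prom[b]), idx[a], idx[b])
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b)
    if best is None:
        return None, n
    a, b = best
    peaks = BandPeaks(
        elm_intensity=float(v[idx[a]]),
        elm_row=int(idx[a]),
        ez_intensity=float(v[idx[b]]),
        ez_row=int(idx[b]),
    )
    return peaks, n


def compute_rezr(peaks: BandPeaks) -> float:
    """rEZR = EZ peak intensity / ELM peak intensity."""
    if peaks.elm_intensity == 0:
        raise ValueError("undefined ratio: ELM peak intensity is zero")
    return float(peaks.ez_intensity / peaks.elm_intensity)


def measure_scan(
    scan: BScan,
    rois: Sequence[ROISpec],
    min_prominence: float = 5.0,
    min_separation_um: float = 10.0,
    band_hints: dict[str, int] | None = None,
) -> list[REZRMeasurement]:
    """Measure rEZR for every ROI of one scan.

    Excluded ROIs propagate their status; profiles in which two qualifying
    peaks cannot be found are recorded as ``peak_failure`` with the number
    of candidates, never silently dropped.  ROIs not yet placed axially
    are placed here (``band_hints`` maps location codes to centre rows).
    """
    from .roi import place_axially

    out = []
    for roi in rois:
        if roi.status == "excluded":
            out.append(
                REZRMeasurement(
                    location=roi.location,
                    scan_index=scan.scan_index,
                    rezr=float("nan"),
                    peaks=None,
                    status="excluded",
                    shift_um=roi.shift_um,
                )
            )
            continue
        if roi.top_row is None:
            hint = (band_hints or {}).get(roi.location.code)
            roi = place_axially(roi, scan, outer_band_hint=hint)
        profile = extract_axial_profile(scan, roi)
        peaks, n_found = detect_band_peaks(profile, min_prominence, min_separation_um)
        if peaks is None:
            out.append(
                REZRMeasurement(
                    location=roi.location,
                    scan_index=scan.scan_index,
                    rezr=float("nan"),
                    peaks=None,
                    status="peak_failure",
                    shift_um=roi.shift_um,
                    n_peaks_found=n_found,
                )
            )
        else:
            out.append(
                REZRMeasurement(
                    location=roi.location,
                    scan_index=scan.scan_index,
                    rezr=compute_rezr(peaks),
                    peaks=peaks,
                    status="ok",
                    shift_um=roi.shift_um,
                    n_peaks_found=n_found,
                )
            )
    return out


def measurements_to_frame(measurements, **tags) -> "pd.DataFrame":
    """Flatten measurements to a table; ``tags`` add constant id columns."""
    import pandas as pd

    rows = []
    for m in measurements:
        rows.append(
            {
                **tags,
                "location": m.location.code,
                "scan_index": m.scan_index,
                "elm": m.peaks.elm_intensity if m.peaks else float("nan"),
                "ez": m.peaks.ez_intensity if m.peaks else float("nan"),
                "rezr": m.rezr,
                "status": m.status,
                "shift_um": m.shift_um,
            }
        )
    return pd.DataFrame(rows)
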
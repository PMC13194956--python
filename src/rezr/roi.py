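"""Planning and adjustment of measurement windows (ROIs) on a B-scan.

The measurement layout samples the foveola, four directions (nasal,
temporal, superior, inferior) at 500 / 1000 / 2000 µm eccentricity, and —
on horizontal scans only — a peripapillary window 3000 µm nasal to the
foveola.  Each window is 15 px wide and 40 px tall by default.  Windows
landing on vessel shadows or disrupted layers are shifted laterally by at
most 100 µm to the nearest fully valid position (ties broken towards the
fovea); if no such position exists the location is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import BScan

__all__ = [
    "Location",
    "ROISpec",
    "plan_rois",
    "adjust_roi",
    "place_axially",
    "detect_shadows",
    "ECCENTRICITIES_UM",
    "PERIPAPILLARY_ECC_UM",
]

ECCENTRICITIES_UM = (500.0, 1000.0, 2000.0)
PERIPAPILLARY_ECC_UM = 3000.0

#: directions measurable on each scan orientation
_DIRECTIONS = {"horizontal": ("nasal", "temporal"), "vertical": ("superior", "inferior")}
_DIR_ABBREV = {"nasal": "n", "temporal": "t", "superior": "s", "inferior": "i"}


@dataclass(frozen=True)
class Location:
    """A named measurement location: direction plus eccentricity in µm."""

    direction: str  # foveola | nasal | temporal | superior | inferior | peripapillary
    eccentricity_um: float = 0.0

    @property
    def code(self) -> str:
        if self.direction in ("foveola", "peripapillary"):
            return self.direction
        return f"{_DIR_ABBREV[self.direction]}{int(self.eccentricity_um)}"

    @classmethod
    def from_code(cls, code: str) -> "Location":
        if code in ("foveola", "peripapillary"):
            ecc = 0.0 if code == "foveola" else PERIPAPILLARY_ECC_UM
            return cls(code, ecc)
        rev = {v: k for k, v in _DIR_ABBREV.items()}
        return cls(rev[code[0]], float(code[1:]))


@dataclass
class ROISpec:
    """A located measurement window and its validity state."""

    location: Location
    centre_col: int
    width_px: int = 15
    height_px: int = 40
    top_row: int | None = None
    status: str = "planned"  # planned | shifted | excluded
    shift_um: float = 0.0
    reason: str | None = None
    clamped: bool = False

    @property
    def columns(self) -> np.ndarray:
        half = self.width_px // 2
        return np.arange(self.centre_col - half, self.centre_col - half + self.width_px)

    @property
    def col_slice(self) -> slice:
        cols = self.columns
        return slice(int(cols[0]), int(cols[-1]) + 1)

    @property
    def row_slice(self) -> slice:
        if self.top_row is None:
            raise ValueError("ROI has not been placed axially (top_row is None)")
        return slice(int(self.top_row), int(self.top_row) + self.height_px)


def _fits(centre: int, width: int, image_width: int) -> bool:
    half = width // 2
    return centre - half >= 0 and centre - half + width <= image_width


def plan_rois(
    scan: BScan,
    width_px: int = 15,
    height_px: int = 40,
    eccentricities_um: Sequence[float] = ECCENTRICITIES_UM,
    peripapillary_um: float = PERIPAPILLARY_ECC_UM,
    nasal_negative_for_right: bool = True,
    superior_negative: bool = True,
) -> list[ROISpec]:
    """Lay out the measurement plan for one scan.

    Horizontal scans get the foveola, nasal/temporal at each eccentricity
    and the peripapillary window (8 locations); vertical scans get the
    foveola and superior/inferior at each eccentricity (7 locations).

    The mapping of anatomical direction to image side depends on how the
    device renders laterality.  By default, for a right eye nasal lies
    towards decreasing column index (mirrored for left eyes) and superior
    towards decreasing column index on vertical scans; both conventions
    are configurable.  Locations whose window would leave the image are
    returned with status ``excluded`` (reason ``"out of field"``) rather
    than raising.
    """
    signs: dict[str, int] = {}
    if scan.orientation == "horizontal":
        nasal = -1 if nasal_negative_for_right else 1
        if scan.eye_side == "left":
            nasal = -nasal
        signs["nasal"] = nasal
        signs["temporal"] = -nasal
    else:
        signs["superior"] = -1 if superior_negative else 1
        signs["inferior"] = -signs["superior"]

    def _make(location: Location, centre: int) -> ROISpec:
        roi = ROISpec(location, int(centre), width_px, height_px)
        if not _fits(roi.centre_col, width_px, scan.width):
            roi.status = "excluded"
            roi.reason = "out of field"
        return roi

    rois = [_make(Location("foveola", 0.0), scan.fovea_col)]
    for direction in _DIRECTIONS[scan.orientation]:
        for ecc in eccentricities_um:
            centre = scan.fovea_col + signs[direction] * round(ecc / scan.lateral_scale)
            rois.append(_make(Location(direction, ecc), centre))
    if scan.orientation == "horizontal":
        centre = scan.fovea_col + signs["nasal"] * round(
            peripapillary_um / scan.lateral_scale
        )
        rois.append(_make(Location("peripapillary", peripapillary_um), centre))
    return rois


def adjust_roi(
    roi: ROISpec,
    validity_mask: np.ndarray,
    lateral_scale: float,
    fovea_col: int,
    max_shift_um: float = 100.0,
) -> ROISpec:
    """Apply the shift-or-exclude rule against a per-column validity mask.

    ``validity_mask`` is True where retinal layers are continuous (no
    vessel shadow or disruption).  If every column of the window is valid
    the ROI is returned unchanged.  Otherwise the centre is moved, in 1-px
    steps, to the nearest position within ``±max_shift_um`` whose window is
    entirely valid; equidistant candidates prefer the fovea-ward side.  If
    no valid position exists the ROI is excluded.
    """
    if roi.status == "excluded":
        return roi
    mask = np.asarray(validity_mask, dtype=bool)
    width = len(mask)
    half = roi.width_px // 2

    def _ok(centre: int) -> bool:
        lo = centre - half
        hi = lo + roi.width_px
        return lo >= 0 and hi <= width and bool(mask[lo:hi].all())

    if _ok(roi.centre_col):
        return roi

    max_px = int(np.floor(max_shift_um / lateral_scale))
    toward_fovea = int(np.sign(fovea_col - roi.centre_col)) or -1
    for step in range(1, max_px + 1):
        for sign in (toward_fovea, -toward_fovea):
            centre = roi.centre_col + sign * step
            if _ok(centre):
                return replace(
                    roi,
                    centre_col=centre,
                    status="shifted",
                    shift_um=float(sign * step * lateral_scale),
                )
    return replace(
        roi,
        status="excluded",
        reason=f"no continuous retinal layers within {max_shift_um:.0f} µm",
    )


def place_axially(
    roi: ROISpec,
    scan: BScan,
    outer_band_hint: int | None = None,
    smooth_rows: int = 5,
) -> ROISpec:
    """Set the window's top row so it spans the outer-retinal complex.

    With ``outer_band_hint`` (a row index at the centre of the band
    complex) the window is centred there.  Otherwise it is centred on the
    depth of maximum smoothed mean intensity of the window's columns,
    searched in the lower half of the image (the outer retina by the
    row-0-is-vitreous convention).  Windows that would overrun the image
    are clamped and flagged.
    """
    if roi.status == "excluded":
        return roi
    if outer_band_hint is None:
        cols = roi.col_slice
        profile = np.asarray(scan.pixels[:, cols], dtype=float).mean(axis=1)
        smoothed = uniform_filter1d(profile, size=smooth_rows)
        lower = scan.height // 2
        centre_row = lower + int(np.argmax(smoothed[lower:]))
    else:
        centre_row = int(round(outer_band_hint))
    top = centre_row - roi.height_px // 2
    clamped_top = int(np.clip(top, 0, scan.height - roi.height_px))
    return replace(roi, top_row=clamped_top, clamped=clamped_top != top)


def detect_shadows(
    scan: BScan, threshold_factor: float = 1.5, background: float | None = None
) -> np.ndarray:
    """Optional automatic validity mask: flag abnormally dark columns.

    A column is invalid when its mean grey value falls below
    ``threshold_factor`` times the background level (estimated as the
    image-wide 10th percentile of column means when not given).  Provided
    as an aid only — it is never applied silently; the pipeline takes
    validity masks from annotations or phantom truth unless the caller
    passes this detector's output explicitly.
    """
    col_means = np.asarray(scan.pixels, dtype=float).mean(axis=0)
    if background is None:
        background = float(np.percentile(col_means, 10))
    return col_means >= threshold_factor * background
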
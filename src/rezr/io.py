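"""Reading, writing and screening of OCT B-scans and eye rosters.

A B-scan is an 8-bit grayscale cross-sectional OCT image.  The coordinate
convention is fixed throughout the package: rows are axial (depth), columns
are lateral, and row 0 is the innermost (vitreous) side — depth increases
with the row index.  Physical scale is never inferred from the image file;
the axial and lateral µm-per-pixel pitch, the fovea column and the scan
orientation are explicit metadata supplied by the caller.

Eye rosters are plain :class:`pandas.DataFrame` tables, one row per eye,
carrying the DR stage, covariates and the screening flags used by
:func:`apply_eligibility`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BScan",
    "read_bscan",
    "write_bscan",
    "pool_npdr",
    "apply_eligibility",
    "STAGES",
    "NPDR_SUBSTAGES",
]

STAGES = ("noDR", "NPDR", "PDR")
NPDR_SUBSTAGES = ("mild", "moderate", "severe")

#: metadata fields that read_bscan refuses to default
REQUIRED_METADATA = ("axial_scale", "lateral_scale", "fovea_col")


@dataclass
class BScan:
    """One OCT B-scan with its physical-scale metadata.

    Parameters
    ----------
    pixels
        2-D array of grey values in [0, 255].  ``uint8`` for images read
        from disk; float arrays are accepted so that noiseless /
        pre-quantisation phantom data can flow through the same code path.
    axial_scale, lateral_scale
        µm per pixel along rows (depth) and columns.
    fovea_col
        Column index of the foveola.
    orientation
        ``"horizontal"`` or ``"vertical"`` scan direction.
    eye_side
        ``"right"`` or ``"left"``.
    scan_index
        1-based index among the consecutive fovea-centred scans (1–3).
    q_score
        Device signal-to-noise quality index (consumed as metadata only).
    """

    pixels: np.ndarray
    axial_scale: float
    lateral_scale: float
    fovea_col: int
    orientation: str = "horizontal"
    eye_side: str = "right"
    scan_index: int = 1
    q_score: float = float("nan")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"B-scan must be a 2-D grayscale image, got {self.pixels.ndim} dims"
            )
        if self.pixels.dtype != np.uint8:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < 0.0 or hi > 255.0:
                raise ValueError(
                    f"grey values must lie in [0, 255]; got range [{lo}, {hi}]"
                )
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("axial_scale and lateral_scale must be positive")
        if not 0 <= int(self.fovea_col) < self.width:
            raise ValueError(
                f"fovea_col {self.fovea_col} outside image width {self.width}"
            )
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.eye_side not in ("right", "left"):
            raise ValueError(f"unknown eye_side {self.eye_side!r}")
        if int(self.scan_index) < 1:
            raise ValueError("scan_index is 1-based")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def metadata(self) -> dict:
        """Scale/position metadata as a plain dict (JSON-serialisable)."""
        return {
            "axial_scale": float(self.axial_scale),
            "lateral_scale": float(self.lateral_scale),
            "fovea_col": int(self.fovea_col),
            "orientation": self.orientation,
            "eye_side": self.eye_side,
            "scan_index": int(self.scan_index),
            "q_score": float(self.q_score),
        }


def read_bscan(path: str | Path, metadata: dict) -> BScan:
    """Read an 8-bit grayscale TIFF or PNG as a :class:`BScan`.

    ``metadata`` must supply ``axial_scale``, ``lateral_scale`` and
    ``fovea_col``; ``orientation``, ``eye_side``, ``scan_index`` and
    ``q_score`` are optional.  Multi-channel or non-8-bit images are
    rejected rather than silently converted.
    """
    path = Path(path)
    missing = [k for k in REQUIRED_METADATA if k not in metadata]
    if missing:
        raise ValueError(f"missing required metadata field(s): {', '.join(missing)}")

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (TIFF or PNG expected)")

    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path.name}: expected 8-bit pixels, got {arr.dtype.itemsize * 8}-bit "
            f"({arr.dtype})"
        )

    allowed = ("orientation", "eye_side", "scan_index", "q_score")
    extras = {k: metadata[k] for k in allowed if k in metadata}
    return BScan(
        pixels=arr,
        axial_scale=float(metadata["axial_scale"]),
        lateral_scale=float(metadata["lateral_scale"]),
        fovea_col=int(metadata["fovea_col"]),
        **extras,
    )


def write_bscan(scan: BScan, path: str | Path) -> Path:
    """Write the pixel grid as 8-bit grayscale TIFF or PNG (by extension)."""
    path = Path(path)
    arr = scan.pixels
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(arr, mode="L").save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# roster operations
# ---------------------------------------------------------------------------

def pool_npdr(records: pd.DataFrame) -> pd.DataFrame:
    """Pool mild/moderate/severe NPDR sub-stages into a single NPDR group.

    The original sub-stage is preserved in an ``npdr_substage`` column.
    Records already labelled with one of the three analysis groups pass
    through unchanged.  Unknown stage labels raise ``ValueError``.
    """
    out = records.copy()
    if len(out) == 0:
        return out
    stages = out["dr_stage"].astype(str)
    unknown = sorted(set(stages) - set(STAGES) - set(NPDR_SUBSTAGES))
    if unknown:
        raise ValueError(f"unknown DR stage label(s): {unknown}")
    if "npdr_substage" not in out.columns:
        out["npdr_substage"] = pd.NA
    sub = stages.isin(NPDR_SUBSTAGES)
    out.loc[sub, "npdr_substage"] = stages[sub]
    out.loc[sub, "dr_stage"] = "NPDR"
    return out


#: exclusion precedence when several flags co-occur (first match wins)
_EXCLUSION_RULES = (
    ("low_quality", "motion artifact or Q-score under threshold"),
    ("dme", "diabetic macular oedema (central subfield thickness over threshold)"),
    ("quiescent_pdr", "quiescent proliferative DR"),
)


def apply_eligibility(
    records: pd.DataFrame,
    q_min: float = 25.0,
    cst_max: float = 250.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a roster into included eyes and excluded eyes with reasons.

    An eye is excluded if (in this order of precedence) it is flagged
    ``low_quality`` or has ``q_score`` below ``q_min``; flagged ``dme`` or
    has ``cst_um`` above ``cst_max``; or flagged ``quiescent_pdr``.  Flag
    and measurement columns are optional — absent columns simply do not
    trigger their rule.  Returns ``(included, excluded)``; the excluded
    frame gains an ``exclusion_reason`` column.  The two frames partition
    the input exactly and the operation is idempotent.
    """
    n = len(records)
    reason = pd.Series([None] * n, index=records.index, dtype=object)

    def _flag(col: str) -> pd.Series:
        if col in records.columns:
            return records[col].fillna(False).astype(bool)
        return pd.Series(False, index=records.index)

    low_q = _flag("low_quality")
    if "q_score" in records.columns:
        low_q |= records["q_score"].astype(float) < q_min
    dme = _flag("dme")
    if "cst_um" in records.columns:
        dme |= records["cst_um"].astype(float) > cst_max
    qpdr = _flag("quiescent_pdr")

    for mask, (col, why) in zip((low_q, dme, qpdr), _EXCLUSION_RULES):
        hit = mask & reason.isna()
        reason[hit] = why

    excluded = records[reason.notna()].copy()
    excluded["exclusion_reason"] = reason[reason.notna()]
    included = records[reason.isna()].copy()
    return included, excluded
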
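"""Run configuration with the analysis defaults, round-tripped via YAML.

Every constant of the measurement protocol lives here with its default:
ROI extent 15 × 40 px, macular eccentricities 500/1000/2000 µm,
peripapillary eccentricity 3000 µm, lateral shift bound 100 µm, peak
prominence 5 grey values, minimum peak separation 10 µm, Q-score floor 25
and central-subfield-thickness ceiling 250 µm.  A config file overrides
any subset; overrides are recorded so a run manifest can state exactly
what deviated from the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # ROI geometry
    roi_width_px: int = 15
    roi_height_px: int = 40
    eccentricities_um: tuple = (500.0, 1000.0, 2000.0)
    peripapillary_um: float = 3000.0
    max_shift_um: float = 100.0
    # peak detection
    min_prominence: float = 5.0
    min_separation_um: float = 10.0
    # eligibility thresholds
    q_min: float = 25.0
    cst_max_um: float = 250.0
    # laterality display conventions
    nasal_negative_for_right: bool = True
    superior_negative: bool = True
    # simulation
    seed: int = 0
    n_eyes_per_group: tuple = (17, 33, 14)
    n_patients: int = 44
    scans_per_eye: int = 3
    # bookkeeping
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("overrides")
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from defaults, an optional YAML file, and overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(RunConfig)} - {"overrides"}
    unknown = sorted(set(values) - valid)
    if unknown:
        raise ValueError(f"unknown config field(s): {', '.join(unknown)}")
    for key in ("eccentricities_um", "n_eyes_per_group"):
        if key in values:
            values[key] = tuple(values[key])
    cfg = RunConfig(**values)
    defaults = RunConfig()
    cfg.overrides = {
        k: v for k, v in cfg.to_dict().items() if v != getattr(defaults, k)
    }
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    d = cfg.to_dict()
    d["eccentricities_um"] = list(d["eccentricities_um"])
    d["n_eyes_per_group"] = list(d["n_eyes_per_group"])
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path
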
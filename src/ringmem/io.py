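"""Canonical trial-record table I/O and run configuration.

The on-disk dialect is a comma-separated file with header::

    subject_id,group,phase,block,trial_index,category,item_id,
    item_status,encoded_angle_deg,response_angle_deg,confidence

Angles are stored in degrees with 4 decimal places; confidence is one of
``1..4`` or ``new`` and present only on delayed-test rows.  Deposited
datasets with other column layouts are mapped onto this dialect by a
thin adapter (`rename_columns`) so the core analysis never depends on an
external schema.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circular import wrap
from .simulate import GroupPreset

__all__ = ["REQUIRED_COLUMNS", "read_trials", "write_trials", "validate_trials",
           "rename_columns", "RunConfig", "read_centers", "write_centers"]

REQUIRED_COLUMNS = [
    "subject_id", "group", "phase", "block", "trial_index", "category",
    "item_id", "item_status", "encoded_angle_deg", "response_angle_deg",
    "confidence",
]

_ENUMS = {
    "group": {"24h", "1week"},
    "phase": {"encode", "immediate", "delayed"},
    "category": {"animal", "object"},
    "item_status": {"old", "new"},
}
_CONFIDENCE = {"1", "2", "3", "4", "new"}


class TrialValidationError(ValueError):
    """Raised with the offending 1-based data line numbers listed."""


def validate_trials(df: pd.DataFrame, offset: int = 2) -> None:
    """Validate a trial table; ``offset`` converts row index to file line.

    Checks column presence, enum values, angle ranges, and the structural
    invariants: foils have no encoded angle and occur only at the delayed
    test; confidence appears only at the delayed test.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    problems = []

    def offenders(mask, what):
        lines = (df.index[mask] + offset).tolist()
        if lines:
            problems.append(f"{what} (lines {lines[:20]}{'...' if len(lines) > 20 else ''})")

    for col, allowed in _ENUMS.items():
        offenders(~df[col].astype(str).isin(allowed), f"invalid {col} value")
    conf = df.confidence
    has_conf = conf.notna() & (conf.astype(str) != "")
    offenders(has_conf & ~conf.astype(str).isin(_CONFIDENCE), "invalid confidence value")
    offenders(has_conf & (df.phase != "delayed"), "confidence outside the delayed test")
    is_new = df.item_status == "new"
    offenders(is_new & df.encoded_angle_deg.notna(), "encoded angle on a new item")
    offenders(is_new & (df.phase != "delayed"), "new item outside the delayed test")
    offenders((~is_new) & df.encoded_angle_deg.isna(), "old item without encoded angle")
    if problems:
        raise TrialValidationError("; ".join(problems))


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; angles are wrapped to [0, 360)."""
    df = pd.read_csv(path, dtype={"confidence": "string"})
    validate_trials(df)
    for col in ("encoded_angle_deg", "response_angle_deg"):
        ok = df[col].notna()
        df.loc[ok, col] = wrap(df.loc[ok, col].astype(float))
    df["confidence"] = df.confidence.astype(object).where(df.confidence.notna(), np.nan)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical dialect (angles to 4 dp)."""
    out = df[REQUIRED_COLUMNS].copy()
    for col in ("encoded_angle_deg", "response_angle_deg"):
        out[col] = out[col].astype(float).round(4)
    out.to_csv(path, index=False)


def rename_columns(df: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Adapter for externally deposited tables: rename columns into the
    canonical dialect and validate the result."""
    out = df.rename(columns=mapping)
    validate_trials(out.reset_index(drop=True))
    return out


def write_centers(designs: dict, path) -> None:
    from .measures import centers_frame

    centers_frame(designs).round(4).to_csv(path, index=False)


def read_centers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"subject_id", "center_animal", "center_object"}
    if not need.issubset(df.columns):
        raise ValueError(f"centers file must have columns {sorted(need)}")
    return df


@dataclass
class RunConfig:
    """Resolved configuration of one simulate/analyze run.

    Round-trips losslessly through YAML; every pipeline run writes the
    resolved config next to its outputs.
    """

    seed: int = 0
    n_subjects: dict = field(default_factory=lambda: {"24h": 28, "1week": 29})
    presets: dict = field(default_factory=dict)  # group -> GroupPreset kwargs
    n_encode_per_category: int = 60
    n_foils_per_category: int = 24
    axis_exclusion: float = 0.0873
    missing_rate: float = 0.03
    hc_band: tuple = (3, 4)
    uniformity_bins: int = 10
    smoothing_sigma_deg: float = 22.0
    exclude_divergence_outliers: bool = True
    out_dir: str = "ringmem_out"

    def group_presets(self) -> dict:
        from .simulate import default_presets

        if not self.presets:
            return default_presets()
        return {g: GroupPreset(group=g, **kw) for g, kw in self.presets.items()}

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["hc_band"] = list(self.hc_band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "hc_band" in d:
            d["hc_band"] = tuple(d["hc_band"])
        return cls(**d)
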
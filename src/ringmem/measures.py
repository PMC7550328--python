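"""Trial- and subject-level behavioral measures.

Four measures, all in degrees on [0, 180] except the correlation:

* **error** — angular distance between an old item's encoded and
  retrieved locations (chance under uniform guessing: 90°);
* **schema-consistency** — angular distance between an old item's
  encoded location and its category's distribution center;
* **schema reliance** — per-subject Pearson correlation between
  schema-consistency and error across tested old items (positive:
  schema-consistent items retrieved more precisely);
* **generalization** — angular distance between a foil's placed location
  and its category center (chance 90°; lower is better).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import angular_distance
from .design import DesignSpec

__all__ = [
    "trial_error",
    "trial_schema_consistency",
    "trial_generalization",
    "add_trial_measures",
    "schema_reliance",
    "classify_confidence",
    "subject_summaries",
    "centers_frame",
]

DEFAULT_HC_BAND = (3, 4)


def centers_frame(designs: dict) -> pd.DataFrame:
    """Per-subject category centers from a ``subject_id -> DesignSpec`` map."""
    return pd.DataFrame(
        {
            "subject_id": list(designs),
            "center_animal": [d.center_animal for d in designs.values()],
            "center_object": [d.center_object for d in designs.values()],
        }
    )


def _own_center(trials: pd.DataFrame, centers) -> np.ndarray:
    """Each trial's own-category center, from a DesignSpec or centers table."""
    if isinstance(centers, DesignSpec):
        ca = np.full(len(trials), centers.center_animal)
        co = np.full(len(trials), centers.center_object)
    else:
        if isinstance(centers, dict):
            centers = centers_frame(centers)
        merged = trials[["subject_id"]].merge(centers, on="subject_id", how="left")
        if merged.center_animal.isna().any():
            missing = trials.subject_id[merged.center_animal.isna()].unique()
            raise ValueError(f"no design centers for subjects {list(missing)}")
        ca = merged.center_animal.to_numpy()
        co = merged.center_object.to_numpy()
    return np.where(trials.category.to_numpy() == "animal", ca, co)


def _require_status(trials: pd.DataFrame, status: str, what: str):
    if (trials.item_status != status).any():
        raise ValueError(f"{what} is defined only for {status!r} items")


def trial_error(trials: pd.DataFrame) -> pd.Series:
    """Retrieval error per old-item trial; NaN where the response is missing."""
    _require_status(trials, "old", "error")
    enc = trials.encoded_angle_deg.to_numpy()
    resp = trials.response_angle_deg.to_numpy()
    out = np.where(np.isnan(resp), np.nan, angular_distance(np.nan_to_num(enc), np.nan_to_num(resp)))
    return pd.Series(out, index=trials.index, name="error")


def trial_schema_consistency(trials: pd.DataFrame, centers) -> pd.Series:
    """Distance from each old item's encoded location to its category center."""
    _require_status(trials, "old", "schema consistency")
    center = _own_center(trials, centers)
    out = angular_distance(trials.encoded_angle_deg.to_numpy(), center)
    return pd.Series(np.atleast_1d(out), index=trials.index, name="schema_consistency")


def trial_generalization(trials: pd.DataFrame, centers) -> pd.Series:
    """Distance from each foil's placed location to its category center."""
    _require_status(trials, "new", "generalization")
    center = _own_center(trials, centers)
    resp = trials.response_angle_deg.to_numpy()
    out = np.where(np.isnan(resp), np.nan,
                   angular_distance(np.nan_to_num(resp), center))
    return pd.Series(np.atleast_1d(out), index=trials.index, name="generalization")


def add_trial_measures(trials: pd.DataFrame, centers) -> pd.DataFrame:
    """Return a copy of the trial table with measure columns attached.

    Old test-phase rows gain ``error`` and ``schema_consistency``; foil
    rows gain ``generalization``; encoding rows only get consistency.
    """
    out = trials.copy()
    out["error"] = np.nan
    out["schema_consistency"] = np.nan
    out["generalization"] = np.nan
    old = out.item_status == "old"
    test = out.phase.isin(["immediate", "delayed"])
    if old.any():
        out.loc[old, "schema_consistency"] = trial_schema_consistency(out[old], centers)
    if (old & test).any():
        out.loc[old & test, "error"] = trial_error(out[old & test])
    new = out.item_status == "new"
    if new.any():
        out.loc[new, "generalization"] = trial_generalization(out[new], centers)
    return out


def schema_reliance(consistency, error, min_trials: int = 3) -> float:
    """Pearson correlation between schema-consistency and error.

    Returns NaN (the undefined flag) when fewer than ``min_trials``
    complete trials are available or either variable has zero variance;
    callers exclude such subjects from across-subject analyses.
    """
    c = np.asarray(consistency, dtype=float)
    e = np.asarray(error, dtype=float)
    ok = ~(np.isnan(c) | np.isnan(e))
    c, e = c[ok], e[ok]
    if c.size < min_trials or np.std(c) == 0 or np.std(e) == 0:
        return float("nan")
    return float(np.corrcoef(c, e)[0, 1])


def classify_confidence(trials: pd.DataFrame, hc_band=DEFAULT_HC_BAND) -> pd.Series:
    """Classify delayed-test old items as HC_hit / LC_hit / miss / none.

    "new" responses to old items are misses; numeric ratings in
    ``hc_band`` are high-confidence hits, others low-confidence; absent
    ratings map to "none".
    """
    _require_status(trials, "old", "confidence classification")
    if (trials.phase != "delayed").any():
        raise ValueError("confidence is collected only at the delayed test")
    hc = {str(b) for b in hc_band}

    def one(v):
        if pd.isna(v):
            return "none"
        v = str(v)
        if v == "new":
            return "miss"
        return "HC_hit" if v in hc else "LC_hit"

    return trials.confidence.map(one).rename("confidence_class")


def subject_summaries(trials: pd.DataFrame, centers,
                      min_trials: int = 3) -> pd.DataFrame:
    """Per-subject, per-phase summary of the behavioral measures.

    One row per subject x test phase with mean_error, schema_reliance and
    (delayed only) mean_generalization.  Divergence is attached
    separately by :func:`ringmem.divergence.divergence_table`.
    """
    m = add_trial_measures(trials, centers)
    m = m[m.phase.isin(["immediate", "delayed"])]
    rows = []
    for (sid, phase), g in m.groupby(["subject_id", "phase"], sort=True):
        old = g[g.item_status == "old"]
        rows.append({
            "subject_id": sid,
            "group": g.group.iloc[0],
            "phase": phase,
            "n_completed": int(old.error.notna().sum()),
            "mean_error": old.error.mean(),
            "schema_reliance": schema_reliance(old.schema_consistency, old.error,
                                               min_trials=min_trials),
            "mean_generalization": g.generalization.mean() if phase == "delayed" else np.nan,
        })
    return pd.DataFrame(rows)
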
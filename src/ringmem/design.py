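"""Experiment design: category centers, cosine-distributed item locations,
and the three trial schedules (encoding, immediate test, delayed test).

The design places items of two categories (animals, objects) on a ring.
Each category's locations are i.i.d. draws from a cosine density
``f(x) = (cos(x - center) + 1) / 2`` (unnormalized; in radians the
normalized density is ``(cos(x - center) + 1) / (2*pi)``), with the two
category centers exactly antipodal.  Because the two cosine densities
with antipodal centers sum to a constant, the pooled location
distribution is analytically uniform — participants cannot learn a
global spatial bias, only the category-conditional structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .circular import angular_distance, wrap

__all__ = [
    "DesignSpec",
    "TrialSchedule",
    "sample_category_centers",
    "sample_cosine_locations",
    "check_pooled_uniformity",
    "build_design_items",
    "build_schedules",
    "CATEGORIES",
]

CATEGORIES = ("animal", "object")

#: cardinal axis angles (degrees) excluded for category centers
_AXES = np.array([0.0, 90.0, 180.0, 270.0])


def sample_category_centers(rng, axis_exclusion_rad: float = 0.0873):
    """Draw the two antipodal category centers, in degrees.

    The first center is uniform on the ring excluding four bands of
    half-width ``axis_exclusion_rad`` around the vertical and horizontal
    axes (resample until valid); the second is exactly 180° away and is
    automatically also outside the bands, since the excluded axis set is
    itself symmetric under a 180° rotation.
    """
    excl_deg = np.rad2deg(axis_exclusion_rad)
    while True:
        c = rng.uniform(0.0, 360.0)
        if np.min(angular_distance(c, _AXES)) >= excl_deg:
            break
    return float(c), float(wrap(c + 180.0))


def sample_cosine_locations(center, n, rng):
    """Draw ``n`` i.i.d. angles (degrees) from the cosine density around
    ``center``.

    Rejection sampling with a uniform envelope: a uniform candidate ``x``
    is accepted with probability ``(cos(x - center) + 1) / 2``, which is
    the unnormalized density divided by its maximum (mean acceptance 1/2).
    """
    n = int(n)
    if n < 0:
        raise ValueError("n must be >= 0")
    out = np.empty(n)
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        x = rng.uniform(0.0, 360.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        acc = x[u < (np.cos(np.deg2rad(x - center)) + 1.0) / 2.0]
        take = min(acc.size, n - got)
        out[got:got + take] = acc[:take]
        got += take
    return out


def check_pooled_uniformity(locations, n_bins: int = 10):
    """Pearson goodness-of-fit test of binned angles against uniformity.

    Returns ``(chi2, p)`` with ``n_bins - 1`` degrees of freedom.  Used
    as the per-participant design check that pooling the two categories'
    cosine draws leaves no learnable global bias.
    """
    locations = np.asarray(locations, dtype=float)
    if locations.size < n_bins:
        import warnings

        warnings.warn(
            f"only {locations.size} locations for {n_bins} bins; "
            "the chi-square approximation is unreliable",
            stacklevel=2,
        )
    counts, _ = np.histogram(wrap(locations), bins=n_bins, range=(0.0, 360.0))
    chi2, p = stats.chisquare(counts)
    return float(chi2), float(p)


@dataclass
class DesignSpec:
    """Parameters of one participant's design.

    ``center_animal``/``center_object`` are in degrees and must be exactly
    antipodal; both must respect the axis-exclusion bands.
    """

    center_animal: float
    center_object: float
    n_encode_per_category: int = 60
    n_foils_per_category: int = 24
    axis_exclusion: float = 0.0873  # radians, half-width of excluded bands
    seed: int = 0

    def __post_init__(self):
        if abs(angular_distance(self.center_animal, self.center_object) - 180.0) > 1e-9:
            raise ValueError("category centers must be exactly 180 degrees apart")
        excl = np.rad2deg(self.axis_exclusion)
        for c in (self.center_animal, self.center_object):
            if np.min(angular_distance(c, _AXES)) < excl - 1e-9:
                raise ValueError(f"center {c} is within the excluded axis bands")
        if self.n_encode_per_category < 0 or self.n_foils_per_category < 0:
            raise ValueError("item counts must be non-negative")

    @classmethod
    def sample(cls, rng, seed: int = 0, **kwargs) -> "DesignSpec":
        """Sample valid centers and build a spec (other fields at defaults)."""
        excl = kwargs.get("axis_exclusion", 0.0873)
        ca, co = sample_category_centers(rng, axis_exclusion_rad=excl)
        return cls(center_animal=ca, center_object=co, seed=seed, **kwargs)

    def center_of(self, category: str) -> float:
        if category == "animal":
            return self.center_animal
        if category == "object":
            return self.center_object
        raise ValueError(f"unknown category {category!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**d)


@dataclass
class TrialSchedule:
    """Ordered trials of one phase.

    ``trials`` columns: item_id, category, item_status, encoded_angle_deg
    (NaN for foils), block, trial_index.
    """

    phase: str
    trials: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.trials)


def build_design_items(spec: DesignSpec, rng) -> pd.DataFrame:
    """Assign a cosine-drawn location to every encoded item; foils get none.

    Returns one row per item: item_id, category, item_status,
    encoded_angle_deg.
    """
    rows = []
    for cat in CATEGORIES:
        locs = sample_cosine_locations(spec.center_of(cat), spec.n_encode_per_category, rng)
        for i, loc in enumerate(locs):
            rows.append((f"{cat[0]}{i + 1:03d}", cat, "old", float(loc)))
        for i in range(spec.n_foils_per_category):
            rows.append((f"{cat[0]}_foil{i + 1:02d}", cat, "new", np.nan))
    return pd.DataFrame(rows, columns=["item_id", "category", "item_status", "encoded_angle_deg"])


def _blocked(df: pd.DataFrame, n_blocks: int, first_block: int = 0) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    per = len(df) // n_blocks
    df["block"] = first_block + df.index // per
    return df


_MAX_SHUFFLE_TRIES = 100_000


def _max_new_run(status: np.ndarray) -> int:
    best = run = 0
    for s in status:
        run = run + 1 if s == "new" else 0
        best = max(best, run)
    return best


def build_schedules(spec: DesignSpec, rng, items: pd.DataFrame | None = None):
    """Build the encoding, immediate-test and delayed-test schedules.

    * encoding: 6 blocks x 60 trials; three cycles, each cycle one random
      permutation of all 120 pairs split into two blocks.
    * immediate: all 120 pairs once, random order, 2 blocks x 60.
    * delayed: 120 old + 48 foils, constrained shuffle (rejection) so that
      no more than two foil trials are consecutive, 3 blocks x 56.

    Returns ``(encode, immediate, delayed)`` :class:`TrialSchedule` and,
    as a fourth element, the item table used.
    """
    if items is None:
        items = build_design_items(spec, rng)
    old = items[items.item_status == "old"]
    cols = ["item_id", "category", "item_status", "encoded_angle_deg"]

    cycles = []
    for cycle in range(3):
        perm = old.sample(frac=1.0, random_state=rng)[cols]
        cycles.append(_blocked(perm, n_blocks=2, first_block=2 * cycle))
    encode = pd.concat(cycles, ignore_index=True)
    encode["trial_index"] = np.arange(len(encode))

    immediate = _blocked(old.sample(frac=1.0, random_state=rng)[cols], n_blocks=2)
    immediate["trial_index"] = np.arange(len(immediate))

    pool = items[cols]
    for _ in range(_MAX_SHUFFLE_TRIES):
        cand = pool.sample(frac=1.0, random_state=rng).reset_index(drop=True)
        if _max_new_run(cand.item_status.to_numpy()) <= 2:
            break
    else:  # pragma: no cover - p(failure) < 1e-300 at the default 120:48 ratio
        raise RuntimeError("could not build a delayed order with <=2 consecutive foils")
    delayed = _blocked(cand, n_blocks=3)
    delayed["trial_index"] = np.arange(len(delayed))

    return (
        TrialSchedule("encode", encode),
        TrialSchedule("immediate", immediate),
        TrialSchedule("delayed", delayed),
        items,
    )
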
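"""Generative model of ring-location responses and a mixture fitter.

Responses are drawn from a three-component mixture per trial:

* **episodic** — von Mises around the item's encoded location
  (concentration ``kappa_epi``),
* **schematic** — von Mises around the item's category center
  (``kappa_schema``),
* **guessing** — uniform on the ring.

Retrieval is modeled hierarchically: an episodic trace is available with
probability ``p_epi``; when it is not, the subject falls back on schema
knowledge with probability ``p_schema``, and otherwise guesses.  The
mixture weights are therefore ``w_epi = p_epi``,
``w_schema = (1 - p_epi) * p_schema`` and the remainder guessing.  Delay
multiplies ``p_epi`` and ``p_schema`` by per-group decay factors; with
episodic memory decaying faster than schema knowledge, the *relative*
contribution of the schema component grows with delay even though
absolute schema knowledge shrinks — the mechanism under the delayed
increase in schema reliance alongside worse generalization.

Foil (never-encoded) items have no episodic component: their weight is
redistributed proportionally to schema and guessing, which in the
hierarchical parameterization is simply ``(p_schema, 1 - p_schema)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .circular import wrap
from .design import DesignSpec, build_schedules

__all__ = [
    "PhaseParams",
    "SubjectParams",
    "GroupPreset",
    "default_presets",
    "simulate_response",
    "simulate_confidence",
    "simulate_cohort",
    "VonMisesMixture",
    "MixtureFit",
    "mixture_pdf",
]

PHASES = ("immediate", "delayed")

# per-component probability of pressing "new" instead of rating confidence
_P_NEW = {"epi": 0.02, "schema": 0.15, "guess": 0.5}
_RATINGS = np.array([1, 2, 3, 4])


@dataclass(frozen=True)
class PhaseParams:
    """Mixture weights and concentrations governing one test phase."""

    w_epi: float
    w_schema: float
    w_guess: float
    kappa_epi: float
    kappa_schema: float

    def __post_init__(self):
        w = np.array([self.w_epi, self.w_schema, self.w_guess])
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("mixture weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()!r}")
        if self.kappa_epi < 0 or self.kappa_schema < 0:
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_retrieval_probs(cls, p_epi, p_schema, kappa_epi, kappa_schema):
        """Build weights from the hierarchical retrieval probabilities."""
        w_epi = float(p_epi)
        w_schema = (1.0 - p_epi) * p_schema
        return cls(w_epi, float(w_schema), float(1.0 - w_epi - w_schema),
                   float(kappa_epi), float(kappa_schema))

    @property
    def weights(self):
        return np.array([self.w_epi, self.w_schema, self.w_guess])

    @property
    def p_schema_fallback(self) -> float:
        """Schema probability conditional on episodic failure (foil weights)."""
        denom = self.w_schema + self.w_guess
        return self.w_schema / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters: one :class:`PhaseParams` per phase."""

    group: str
    phases: dict  # phase name -> PhaseParams
    confidence_gain: float = 1.0

    def for_phase(self, phase: str) -> PhaseParams:
        return self.phases[phase]


@dataclass(frozen=True)
class GroupPreset:
    """Population-level parameters for one delay group.

    ``p_epi``/``p_schema`` are the immediate-test retrieval probabilities;
    ``epi_decay``/``schema_decay`` multiply them (and, with a square-root
    exponent, the concentrations) at the delayed test.  Heterogeneity
    across subjects comes from a shared latent "memory ability" that
    shifts both retrieval probabilities on the logit scale — this is what
    couples episodic precision and generalization across subjects.
    """

    group: str
    p_epi: float = 0.80
    p_schema: float = 0.60
    kappa_epi: float = 12.0
    kappa_schema: float = 6.0
    epi_decay: float = 0.85
    schema_decay: float = 0.97
    confidence_gain: float = 1.0
    ability_sd: float = 0.6
    idiosyncrasy_sd: float = 0.3
    kappa_sd: float = 0.25  # lognormal sigma on concentrations

    def __post_init__(self):
        if not (0 < self.epi_decay <= 1 and 0 < self.schema_decay <= 1):
            raise ValueError("decay factors must lie in (0, 1]")

    def draw_subject(self, rng) -> SubjectParams:
        a = rng.normal(0.0, self.ability_sd)
        p_epi = _logistic(_logit(self.p_epi) + a + rng.normal(0, self.idiosyncrasy_sd))
        p_schema = _logistic(_logit(self.p_schema) + a + rng.normal(0, self.idiosyncrasy_sd))
        ke = self.kappa_epi * rng.lognormal(0.0, self.kappa_sd)
        ks = self.kappa_schema * rng.lognormal(0.0, self.kappa_sd)
        phases = {
            "immediate": PhaseParams.from_retrieval_probs(p_epi, p_schema, ke, ks),
            "delayed": PhaseParams.from_retrieval_probs(
                p_epi * self.epi_decay,
                p_schema * self.schema_decay,
                ke * math.sqrt(self.epi_decay),
                ks * math.sqrt(self.schema_decay),
            ),
        }
        return SubjectParams(self.group, phases, self.confidence_gain)


def default_presets() -> dict:
    """Default cohort presets: episodic memory decays faster than schema.

    The 1-week group decays both components more than the 24-h group, and
    in both groups ``epi_decay < schema_decay``.
    """
    return {
        "24h": GroupPreset(group="24h", epi_decay=0.85, schema_decay=0.97),
        "1week": GroupPreset(group="1week", epi_decay=0.45, schema_decay=0.80),
    }


def _logit(p):
    return math.log(p / (1.0 - p))


def _logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


def _component_weights(params: PhaseParams, is_old: np.ndarray) -> np.ndarray:
    """(n, 3) weight matrix over (epi, schema, guess); foils get no epi."""
    n = is_old.size
    w = np.empty((n, 3))
    w[is_old] = (params.w_epi, params.w_schema, params.w_guess)
    ps = params.p_schema_fallback
    w[~is_old] = (0.0, ps, 1.0 - ps)
    return w


def simulate_response(encoded_deg, center_deg, params: PhaseParams, rng,
                      return_components: bool = False):
    """Simulate responses (degrees) for a vector of trials.

    ``encoded_deg`` may contain NaN for foil trials; those trials draw
    only from the schema/guess components.
    """
    encoded = np.atleast_1d(np.asarray(encoded_deg, dtype=float))
    center = np.broadcast_to(np.asarray(center_deg, dtype=float), encoded.shape)
    is_old = ~np.isnan(encoded)
    w = _component_weights(params, is_old)
    u = rng.uniform(size=encoded.size)
    comp = (u[:, None] >= np.cumsum(w, axis=1)).sum(axis=1)  # 0=epi 1=schema 2=guess

    mu = np.where(comp == 0, encoded, np.where(comp == 1, center, 0.0))
    kappa = np.where(comp == 0, params.kappa_epi,
                     np.where(comp == 1, params.kappa_schema, 0.0))
    resp = wrap(np.rad2deg(rng.vonmises(np.deg2rad(mu), kappa)))
    resp = np.atleast_1d(resp)
    if return_components:
        return resp, np.array(["epi", "schema", "guess"])[comp]
    return resp


def simulate_confidence(components, params: PhaseParams, confidence_gain, rng):
    """Simulate the delayed-test confidence report per trial.

    Returns an object array over ``{"1","2","3","4","new"}``.  The
    subject presses "new" with a per-component probability (highest when
    guessing), otherwise rates on the 4-point scale via a softmax whose
    sharpness grows with the drawn component's expected precision — so
    episodic draws earn high ratings, guesses rate near-uniformly, and
    high-confidence trials end up more precise on average.
    """
    components = np.asarray(components)
    n = components.size
    out = np.empty(n, dtype=object)
    p_new = np.array([_P_NEW[c] for c in components])
    is_new = rng.uniform(size=n) < p_new

    strength = np.where(
        components == "epi", math.log1p(params.kappa_epi),
        np.where(components == "schema", math.log1p(params.kappa_schema), 0.0),
    )
    grade = (_RATINGS - 2.5) / 1.5  # [-1, -1/3, 1/3, 1]
    logits = confidence_gain * strength[:, None] * grade[None, :]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    ratings = _RATINGS[(u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)]

    out[is_new] = "new"
    out[~is_new] = [str(r) for r in ratings[~is_new]]
    return out


TRIAL_COLUMNS = [
    "subject_id", "group", "phase", "block", "trial_index", "category",
    "item_id", "item_status", "encoded_angle_deg", "response_angle_deg",
    "confidence",
]


def _phase_rows(subject_id, group, phase, sched, centers, params, gain,
                rng, missing_rate):
    df = sched.trials.copy()
    enc = df.encoded_angle_deg.to_numpy()
    center = np.where(df.category.to_numpy() == "animal", centers[0], centers[1])
    resp, comp = simulate_response(enc, center, params, rng, return_components=True)
    conf = np.full(len(df), np.nan, dtype=object)
    if phase == "delayed":
        conf = simulate_confidence(comp, params, gain, rng)
    if missing_rate > 0:
        miss = rng.uniform(size=len(df)) < missing_rate
        resp = resp.astype(float)
        resp[miss] = np.nan
        conf[miss] = np.nan
    df["subject_id"] = subject_id
    df["group"] = group
    df["phase"] = phase
    df["response_angle_deg"] = resp
    df["confidence"] = conf
    return df[TRIAL_COLUMNS]


def simulate_cohort(presets: dict | None = None, n_subjects: dict | None = None,
                    seed: int = 0, missing_rate: float = 0.03,
                    design_kwargs: dict | None = None):
    """Simulate a full two-group cohort.

    Defaults mirror the study conditions: 28 subjects in the 24-h group
    and 29 in the 1-week group, each with their own randomly placed
    category centers, 120 encoded pairs, three test phases, and ~3% of
    responses missing completely at random.

    Returns ``(trials, designs, subject_params)`` where ``trials`` is the
    canonical trial-record table, ``designs`` maps subject_id ->
    :class:`DesignSpec` and ``subject_params`` maps subject_id ->
    :class:`SubjectParams`.
    """
    presets = presets if presets is not None else default_presets()
    n_subjects = n_subjects if n_subjects is not None else {"24h": 28, "1week": 29}
    design_kwargs = design_kwargs or {}
    root = np.random.SeedSequence(seed)
    group_names = sorted(presets)
    group_seqs = dict(zip(group_names, root.spawn(len(group_names))))
    frames, designs, subject_params = [], {}, {}
    for group in group_names:
        preset = presets[group]
        n = n_subjects[group]
        for i, child in enumerate(group_seqs[group].spawn(n)):
            rng = np.random.default_rng(child)
            sid = f"{group}_s{i + 1:02d}"
            spec = DesignSpec.sample(rng, seed=seed, **design_kwargs)
            encode, immediate, delayed, items = build_schedules(spec, rng)
            params = preset.draw_subject(rng)
            centers = (spec.center_animal, spec.center_object)

            # encoding phase: guided placement onto the marked location
            enc_df = encode.trials.copy()
            enc_df["subject_id"] = sid
            enc_df["group"] = group
            enc_df["phase"] = "encode"
            enc_df["response_angle_deg"] = enc_df.encoded_angle_deg
            enc_df["confidence"] = np.nan
            frames.append(enc_df[TRIAL_COLUMNS])

            frames.append(_phase_rows(sid, group, "immediate", immediate, centers,
                                      params.for_phase("immediate"),
                                      params.confidence_gain, rng, missing_rate))
            frames.append(_phase_rows(sid, group, "delayed", delayed, centers,
                                      params.for_phase("delayed"),
                                      params.confidence_gain, rng, missing_rate))
            designs[sid] = spec
            subject_params[sid] = params
    trials = pd.concat(frames, ignore_index=True)
    return trials, designs, subject_params


# ---------------------------------------------------------------------------
# mixture density and maximum-likelihood fitting


def _vm_logpdf(x_rad, mu_rad, kappa):
    """log von Mises density, numerically stable for large kappa."""
    return kappa * (np.cos(x_rad - mu_rad) - 1.0) - np.log(2 * np.pi * special.i0e(kappa))


def mixture_pdf(x_deg, encoded_deg, center_deg, params: PhaseParams):
    """Mixture density (per radian) of a response at ``x_deg`` for one trial."""
    x = np.deg2rad(np.asarray(x_deg, dtype=float))
    enc = np.deg2rad(encoded_deg)
    cen = np.deg2rad(center_deg)
    return (params.w_epi * np.exp(_vm_logpdf(x, enc, params.kappa_epi))
            + params.w_schema * np.exp(_vm_logpdf(x, cen, params.kappa_schema))
            + params.w_guess / (2 * np.pi))


def _a_inv(r):
    """Approximate inverse of A(kappa) = I1/I0 (Best & Fisher)."""
    r = min(max(r, 0.0), 1.0 - 1e-9)
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


@dataclass
class MixtureFit:
    """Result of fitting the episodic/schema/guess mixture to one subject."""

    w_epi: float
    w_schema: float
    w_guess: float
    kappa_epi: float
    kappa_schema: float
    log_likelihood: float
    n_trials: int
    converged: bool
    degenerate: bool = False

    @property
    def weights(self):
        return np.array([self.w_epi, self.w_schema, self.w_guess])


class VonMisesMixture:
    """Maximum-likelihood fit of the three-component response mixture.

    Expectation–maximization over (weights, kappa_epi, kappa_schema) with
    a small multi-start over initial concentrations; the episodic
    component's mean is pinned to each trial's encoded angle and the
    schematic component's mean to the category center, so the only free
    parameters are the two concentrations and the weight simplex.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-8,
                 kappa_inits=(2.0, 8.0, 32.0), max_kappa: float = 1e6):
        self.max_iter = max_iter
        self.tol = tol
        self.kappa_inits = kappa_inits
        self.max_kappa = max_kappa

    def fit(self, responses_deg, encoded_deg, center_deg) -> MixtureFit:
        """Fit to one subject's old-item trials.

        Parameters are angles in degrees; ``center_deg`` may be a scalar
        or per-trial array (items of both categories can be pooled by
        passing each trial's own category center).
        """
        r = np.deg2rad(np.asarray(responses_deg, dtype=float))
        e = np.deg2rad(np.asarray(encoded_deg, dtype=float))
        c = np.deg2rad(np.broadcast_to(np.asarray(center_deg, dtype=float), r.shape))
        ok = ~(np.isnan(r) | np.isnan(e))
        r, e, c = r[ok], e[ok], c[ok]
        n = r.size
        if n < 3:
            raise ValueError("need at least 3 complete trials to fit the mixture")
        if n < 50:
            import warnings

            warnings.warn(f"only {n} trials; mixture estimates will be imprecise",
                          stacklevel=2)
        degenerate = np.allclose(r, r[0])

        best = None
        for k0 in self.kappa_inits:
            fit = self._em(r, e, c, k0)
            if best is None or fit.log_likelihood > best.log_likelihood:
                best = fit
        best.degenerate = bool(degenerate)
        return best

    def log_likelihood(self, params: PhaseParams, responses_deg, encoded_deg,
                       center_deg) -> float:
        """Log-likelihood of arbitrary parameters on the same data layout."""
        r = np.asarray(responses_deg, dtype=float)
        c = np.broadcast_to(np.asarray(center_deg, dtype=float), r.shape)
        pdf = mixture_pdf(r, np.asarray(encoded_deg, dtype=float), c, params)
        return float(np.sum(np.log(pdf)))

    def _em(self, r, e, c, kappa0):
        n = r.size
        w = np.array([1 / 3, 1 / 3, 1 / 3])
        ke = ks = float(kappa0)
        log_guess = np.full(n, -np.log(2 * np.pi))
        prev_ll = -np.inf
        converged = False
        for _ in range(self.max_iter):
            logp = np.column_stack([
                np.log(w[0] + 1e-300) + _vm_logpdf(r, e, ke),
                np.log(w[1] + 1e-300) + _vm_logpdf(r, c, ks),
                np.log(w[2] + 1e-300) + log_guess,
            ])
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            tot = p.sum(axis=1, keepdims=True)
            ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
            gamma = p / tot

            w = gamma.mean(axis=0)
            ge, gs = gamma[:, 0].sum(), gamma[:, 1].sum()
            if ge > 1e-10:
                ke = min(_a_inv(float(gamma[:, 0] @ np.cos(r - e) / ge)), self.max_kappa)
            if gs > 1e-10:
                ks = min(_a_inv(float(gamma[:, 1] @ np.cos(r - c) / gs)), self.max_kappa)
            if ll - prev_ll < self.tol and ll >= prev_ll:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        return MixtureFit(float(w[0]), float(w[1]), float(w[2]), ke, ks,
                          prev_ll, n, converged)


def fit_mixture(responses_deg, encoded_deg, center_deg, **kwargs) -> MixtureFit:
    """Functional wrapper over :class:`VonMisesMixture`."""
    return VonMisesMixture(**kwargs).fit(responses_deg, encoded_deg, center_deg)
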
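"""Inferential layer: chance tests, effect sizes, correlation contrasts,
across-subject regressions, the mixed-design divergence ANOVA, and
trial-level linear mixed models.

Conventions follow the behavioral-memory literature: two-tailed tests
throughout, Cohen's d for t-tests (``d = t / sqrt(n)`` for a one-sample
test), partial eta squared for ANOVA effects, and no multiple-testing
correction.  Mixed-model optimization is delegated to statsmodels
(REML); this module owns the model specification, the joint
standardization of predictors, the random-structure fallback ladder and
the contrast machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "fisher_z_compare",
    "pearson_r",
    "across_subject_regression",
    "anova_2x2",
    "ModelSpec",
    "MixedModelResult",
    "fit_mixed_model",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float
    n: int
    degenerate: bool = False

    def as_dict(self, prefix: str = "") -> dict:
        return {prefix + k: v for k, v in (
            ("statistic", self.statistic), ("df", self.df),
            ("p_value", self.p_value), ("effect_size", self.effect_size),
            ("n", self.n))}


def one_sample_t(values, mu: float = 90.0) -> TestResult:
    """Two-tailed one-sample t-test; effect size d = (mean - mu)/SD = t/sqrt(n).

    The 90° default is the chance level for both error and generalization
    (mean angular distance of a uniform response from any fixed point).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        if v[0] == mu:
            return TestResult(0.0, n - 1, 1.0, 0.0, n, degenerate=True)
        t = math.inf if v[0] > mu else -math.inf
        return TestResult(t, n - 1, 0.0, t, n, degenerate=True)
    t = (v.mean() - mu) / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), n - 1, float(p), float(t / math.sqrt(n)), n)


def paired_t(a, b) -> TestResult:
    """Two-tailed paired t-test of a - b; d = mean diff / SD of diffs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    return one_sample_t(a[ok] - b[ok], mu=0.0)


def two_sample_t(a, b) -> TestResult:
    """Welch-free classical two-sample t with pooled-SD Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    t, p = sps.ttest_ind(a, b, equal_var=True)
    sp = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else math.nan
    return TestResult(float(t), na + nb - 2, float(p), float(d), na + nb)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two independent Pearson correlations via Fisher's z.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``, two-tailed
    p from the standard normal.  Antisymmetric in the two samples.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in each sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * sps.norm.sf(abs(z)))


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with its t-test (df = n - 2, effect size r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    r, p = sps.pearsonr(x, y)
    n = x.size
    t = r * math.sqrt((n - 2) / (1 - r ** 2)) if abs(r) < 1 else math.inf
    return TestResult(float(t), n - 2, float(p), float(r), n)


def across_subject_regression(data: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Ordinary least squares across subjects with a patsy formula.

    Two-level group factors are coded as treatment contrasts.  Returns a
    tidy coefficient table (term, estimate, se, t, p, df).  A rank
    deficient design raises an error naming the collinear columns.
    """
    import statsmodels.formula.api as smf

    model = smf.ols(formula, data=data.dropna(
        subset=[c for c in data.columns if c in formula]))
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = [name for j, name in enumerate(model.exog_names)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"singular design; collinear terms: {bad}")
    res = model.fit()
    return pd.DataFrame({
        "term": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
        "df": res.df_resid,
    })


def anova_2x2(table: pd.DataFrame, dv: str = "divergence", within: str = "phase",
              between: str = "group", subject: str = "subject_id") -> pd.DataFrame:
    """Mixed-design 2x2 ANOVA (between group x within time) with partial
    eta squared.

    Subjects missing either level of the within factor are dropped (and
    reported via a warning) so the repeated-measures decomposition stays
    balanced within subject.
    """
    import pingouin as pg

    wide_counts = table.groupby(subject)[within].nunique()
    n_levels = table[within].nunique()
    incomplete = wide_counts[wide_counts < n_levels].index.tolist()
    if incomplete:
        warnings.warn(f"dropping subjects with incomplete cells: {incomplete}",
                      stacklevel=2)
        table = table[~table[subject].isin(incomplete)]
    aov = pg.mixed_anova(data=table, dv=dv, within=within, between=between,
                         subject=subject)
    out = aov.rename(columns={"Source": "effect", "DF1": "df1", "DF2": "df2",
                              "p-unc": "p", "p_unc": "p", "np2": "partial_eta_sq"})
    return out[["effect", "df1", "df2", "F", "p", "partial_eta_sq"]]


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class ModelSpec:
    """Specification of a trial-level linear mixed model.

    ``fixed`` is a patsy right-hand side (e.g.
    ``"schema_consistency * phase"``); every predictor named in
    ``random_slopes`` gets a per-subject random slope in addition to the
    per-subject random intercept.  Variables in ``standardize`` are
    z-scored jointly across all trials and participants before fitting
    (a convergence aid that leaves t statistics of affine-equivariant
    terms unchanged).
    """

    dependent: str
    fixed: str
    random_slopes: list = field(default_factory=list)
    standardize: list = field(default_factory=list)
    subject: str = "subject_id"


@dataclass
class MixedModelResult:
    table: pd.DataFrame
    spec: ModelSpec
    n_obs: int
    n_subjects: int
    dropped_slopes: list
    converged: bool
    result: object = field(repr=False, default=None)  # statsmodels results

    def contrast(self, weights: dict) -> TestResult:
        """t-test of a linear combination of fixed effects.

        ``weights`` maps design-column names to coefficients, e.g. the
        consistency simple slope within one phase is
        ``{"consistency": 1, "consistency:phase[T.delayed]": level}``.
        Degrees of freedom take the smallest df among the involved terms.
        """
        params = self.result.fe_params
        cov = self.result.cov_params().loc[params.index, params.index]
        L = pd.Series(0.0, index=params.index)
        for name, w in weights.items():
            if name not in L.index:
                raise KeyError(f"no fixed effect {name!r}; have {list(L.index)}")
            L[name] = w
        est = float(L @ params)
        se = float(np.sqrt(L @ cov.to_numpy() @ L))
        df = float(self.table.set_index("term").loc[
            [n for n, w in weights.items() if w != 0], "df"].min())
        t = est / se
        p = 2 * sps.t.sf(abs(t), df)
        return TestResult(t, df, float(p), est, self.n_obs)


def _zscore(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def _term_df(name: str, col: np.ndarray, groups: np.ndarray, spec: ModelSpec,
             n_obs: int, n_subj: int, rank: int) -> float:
    """Containment-style degrees of freedom for one fixed-effect column.

    Between-subject columns (constant within every subject) and columns
    carrying a per-subject random slope are tested at the subject level;
    purely within-subject columns without a random slope are tested at
    the observation level.  This mirrors where each effect's replication
    actually lives and approximates Satterthwaite df in the two regimes
    that matter here (see docs/methods.md).
    """
    u = pd.Series(col).groupby(pd.Series(groups)).nunique()
    between = bool((u <= 1).all())
    sloped = any(v in name for v in spec.random_slopes)
    if between or sloped:
        return max(n_subj - 2, 1)
    return max(n_obs - rank, 1)


def fit_mixed_model(trials: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML linear mixed model with per-subject random intercepts and the
    requested random slopes.

    Convergence failures trigger a fallback ladder: random slopes are
    dropped one at a time (last first) and the reduced model is refit; a
    final fallback keeps only the random intercept.  Every drop is
    recorded in ``dropped_slopes`` and warned about.
    """
    import statsmodels.formula.api as smf

    data = trials.copy()
    cols = [spec.dependent] + [c for c in data.columns
                               if c in spec.fixed or c == spec.subject]
    data = data.dropna(subset=[c for c in set(cols) if c in data.columns])
    for v in spec.standardize:
        data[v] = _zscore(data[v].astype(float))

    formula = f"{spec.dependent} ~ {spec.fixed}"
    ladder = [list(spec.random_slopes)[:k]
              for k in range(len(spec.random_slopes), -1, -1)]
    dropped, res, used = [], None, None
    for slopes in ladder:
        re_formula = "~" + (" + ".join(slopes) if slopes else "1")
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(formula, data=data,
                                        groups=data[spec.subject],
                                        re_formula=re_formula)
                    cand = model.fit(reml=True, method=method, maxiter=500)
                if cand.converged and np.all(np.isfinite(cand.bse_fe)):
                    res, used = cand, slopes
                    break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is not None:
            break
        dropped.append(slopes[-1] if slopes else "(intercept-only failed)")
    if res is None:
        raise RuntimeError(
            "mixed model failed to converge even with random intercepts only; "
            f"dropped slopes in order: {dropped}")
    if dropped:
        warnings.warn(f"random slopes dropped for convergence: {dropped}",
                      stacklevel=2)

    groups = data[spec.subject].to_numpy()
    n_obs, n_subj = len(data), data[spec.subject].nunique()
    fe = res.fe_params
    exog = pd.DataFrame(res.model.exog, columns=res.model.exog_names)
    rank = np.linalg.matrix_rank(res.model.exog)
    rows = []
    sub_spec = ModelSpec(spec.dependent, spec.fixed, used, spec.standardize,
                         spec.subject)
    for name in fe.index:
        est, se = fe[name], res.bse_fe[name]
        df = _term_df(name, exog[name].to_numpy(), groups, sub_spec, n_obs,
                      n_subj, rank)
        t = est / se
        rows.append({"term": name, "estimate": est, "se": se, "df": df,
                     "t": t, "p": 2 * sps.t.sf(abs(t), df)})
    return MixedModelResult(pd.DataFrame(rows), spec, n_obs, n_subj,
                            dropped, True, res)
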
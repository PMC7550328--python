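"""End-to-end orchestration: simulate -> measure -> test -> report.

`run_pipeline` takes a :class:`~ringmem.io.RunConfig` (and optionally an
already-loaded trial table) and produces a results bundle: the trial
table, per-subject summaries, the divergence table, and a tidy table of
every inferential test, plus a run log.  All randomness flows from the
config's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import stats as st
from .io import RunConfig, write_centers, write_trials
from .measures import add_trial_measures, centers_frame, subject_summaries
from .simulate import simulate_cohort

__all__ = ["ResultsBundle", "run_pipeline", "simulate_trials", "stats_battery"]


@dataclass
class ResultsBundle:
    config: RunConfig
    trials: pd.DataFrame = field(repr=False)
    summaries: pd.DataFrame = field(repr=False)
    divergence: pd.DataFrame = field(repr=False)
    tests: pd.DataFrame = field(repr=False)
    log: list = field(default_factory=list)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(self.trials, out / "trials.csv")
        self.summaries.round(6).to_csv(out / "subject_summaries.csv", index=False)
        self.divergence.round(6).to_csv(out / "divergence.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.config.to_yaml(out / "config.yaml")
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        return out


def simulate_trials(config: RunConfig):
    """Simulate a cohort under the config; returns (trials, centers table)."""
    trials, designs, _ = simulate_cohort(
        presets=config.group_presets(),
        n_subjects=config.n_subjects,
        seed=config.seed,
        missing_rate=config.missing_rate,
        design_kwargs={
            "n_encode_per_category": config.n_encode_per_category,
            "n_foils_per_category": config.n_foils_per_category,
            "axis_exclusion": config.axis_exclusion,
        },
    )
    return trials, centers_frame(designs)


def _row(analysis, term, tr: st.TestResult, note=""):
    return {"analysis": analysis, "term": term, "estimate": tr.effect_size,
            "se": np.nan, "df": tr.df, "statistic": tr.statistic,
            "p": tr.p_value, "n": tr.n, "note": note}


def _mixed_rows(analysis, mm: st.MixedModelResult):
    t = mm.table.copy()
    t.insert(0, "analysis", analysis)
    t["n"] = mm.n_obs
    t["note"] = ("slopes dropped: " + ",".join(mm.dropped_slopes)
                 if mm.dropped_slopes else "")
    return t.rename(columns={"t": "statistic"})[
        ["analysis", "term", "estimate", "se", "df", "statistic", "p", "n", "note"]]


def _consistency_simple_slopes(analysis, mm: st.MixedModelResult, log):
    """Consistency slope within each phase, from the fitted interactions."""
    rows = []
    terms = list(mm.result.fe_params.index)
    inter = [t for t in terms
             if set(t.split(":")) >= {"schema_consistency"} and "phase" in t
             and t.count(":") == 1]
    base_phase = "delayed" if any("immediate" in t for t in inter) else "immediate"
    rows.append(_row(analysis, f"consistency slope @ {base_phase}",
                     mm.contrast({"schema_consistency": 1.0}), "simple effect"))
    for t in inter:
        level = t.split("[T.")[-1].rstrip("]")
        rows.append(_row(analysis, f"consistency slope @ {level}",
                         mm.contrast({"schema_consistency": 1.0, t: 1.0}),
                         "simple effect"))
    log.append(f"{analysis}: simple slopes at phases relative to {base_phase}")
    return rows


def stats_battery(measured: pd.DataFrame, summaries: pd.DataFrame,
                  div_table: pd.DataFrame, config: RunConfig, log: list):
    """Every test-phase analysis of the study, as one tidy table."""
    rows = []

    # chance tests of error and generalization per group (and phase for error)
    for (group, phase), g in summaries.groupby(["group", "phase"]):
        rows.append(_row("error vs chance", f"{group}/{phase}",
                         st.one_sample_t(g.mean_error, 90.0), "H0: mean=90"))
    for group, g in summaries[summaries.phase == "delayed"].groupby("group"):
        rows.append(_row("generalization vs chance", group,
                         st.one_sample_t(g.mean_generalization, 90.0), "H0: mean=90"))

    # trial-level mixed models of error
    test_old = measured[(measured.item_status == "old")
                        & measured.phase.isin(["immediate", "delayed"])]
    mspec = st.ModelSpec(
        dependent="error",
        fixed="schema_consistency * phase * group",
        random_slopes=["schema_consistency"],
        standardize=["error", "schema_consistency"],
    )
    mm = st.fit_mixed_model(test_old, mspec)
    rows += _mixed_rows("mixed: error ~ consistency*phase*group", mm).to_dict("records")
    for group, g in test_old.groupby("group"):
        spec_g = st.ModelSpec("error", "schema_consistency * phase",
                              random_slopes=["schema_consistency"],
                              standardize=["error", "schema_consistency"])
        mm_g = st.fit_mixed_model(g, spec_g)
        name = f"mixed: error ~ consistency*phase [{group}]"
        rows += _mixed_rows(name, mm_g).to_dict("records")
        rows += _consistency_simple_slopes(name, mm_g, log)

    # generalization group contrast (trial-level, random intercepts)
    foils = measured[measured.item_status == "new"].dropna(subset=["generalization"])
    mm_gen = st.fit_mixed_model(
        foils, st.ModelSpec("generalization", "group", standardize=[]))
    rows += _mixed_rows("mixed: generalization ~ group", mm_gen).to_dict("records")

    # divergence: 2x2 mixed ANOVA and per-group time contrasts
    variants = [("all subjects", div_table)]
    if config.exclude_divergence_outliers:
        flagged = dv.flag_divergence_outliers(div_table)
        if flagged:
            log.append(f"divergence outliers excluded in variant: {sorted(flagged)}")
            variants.append(("outliers excluded",
                             div_table[~div_table.subject_id.isin(flagged)]))
    for label, tab in variants:
        aov = st.anova_2x2(tab)
        for _, r in aov.iterrows():
            rows.append({"analysis": f"divergence ANOVA ({label})",
                         "term": r.effect, "estimate": r.partial_eta_sq,
                         "se": np.nan, "df": f"{r.df1:g},{r.df2:g}",
                         "statistic": r.F, "p": r.p, "n": tab.subject_id.nunique(),
                         "note": "partial eta^2 in estimate"})
        wide = tab.pivot(index="subject_id", columns="phase", values="divergence")
        grp = tab.drop_duplicates("subject_id").set_index("subject_id").group
        for group in sorted(grp.unique()):
            w = wide[grp == group]
            rows.append(_row(f"divergence delayed vs immediate ({label})", group,
                             st.paired_t(w["delayed"], w["immediate"])))

    # across-subject regressions and correlations at the delayed test
    delayed = summaries[summaries.phase == "delayed"].dropna(
        subset=["mean_error", "schema_reliance", "mean_generalization"])
    for formula in ("mean_generalization ~ mean_error * group",
                    "mean_generalization ~ schema_reliance * group",
                    "mean_generalization ~ mean_error + schema_reliance + group"):
        coefs = st.across_subject_regression(delayed, formula)
        for _, r in coefs.iterrows():
            rows.append({"analysis": f"OLS: {formula}", "term": r.term,
                         "estimate": r.estimate, "se": r.se, "df": r.df,
                         "statistic": r.t, "p": r.p, "n": len(delayed), "note": ""})
    for var in ("mean_error", "schema_reliance"):
        rs = {}
        for group, g in delayed.groupby("group"):
            tr = st.pearson_r(g[var], g.mean_generalization)
            rs[group] = (tr.effect_size, tr.n)
            rows.append(_row(f"r({var}, generalization)", group, tr, "r in estimate"))
        if len(rs) == 2:
            (r1, n1), (r2, n2) = (rs[k] for k in sorted(rs))
            z, p = st.fisher_z_compare(r1, n1, r2, n2)
            rows.append({"analysis": f"r({var}, generalization)",
                         "term": "group difference (Fisher z)", "estimate": r1 - r2,
                         "se": np.nan, "df": np.nan, "statistic": z, "p": p,
                         "n": n1 + n2, "note": f"{sorted(rs)[0]} vs {sorted(rs)[1]}"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, trials: pd.DataFrame | None = None,
                 centers: pd.DataFrame | None = None,
                 write: bool = False) -> ResultsBundle:
    """Run the full analysis; simulates a cohort if no trials are given."""
    log = [f"seed={config.seed}"]
    if trials is None:
        trials, centers = simulate_trials(config)
        log.append(f"simulated cohort: {trials.subject_id.nunique()} subjects, "
                   f"{len(trials)} trials")
    elif centers is None:
        raise ValueError("centers must accompany an externally provided trial table")

    measured = add_trial_measures(trials, centers)
    summaries = subject_summaries(trials, centers)
    n_undef = int(summaries.schema_reliance.isna().sum())
    if n_undef:
        log.append(f"{n_undef} subject-phase reliance values undefined (excluded)")
    div_table = dv.divergence_table(trials, sigma_deg=config.smoothing_sigma_deg)
    summaries = summaries.merge(div_table, on=["subject_id", "group", "phase"],
                                how="left")
    tests = stats_battery(measured, summaries, div_table, config, log)
    log.append(f"computed {len(tests)} test rows")
    bundle = ResultsBundle(config, trials, summaries, div_table, tests, log)
    if write:
        bundle.write(config.out_dir)
    return bundle
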
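import math

import numpy as np
import pandas as pd
import pytest

from ringmem.stats import (ModelSpec, anova_2x2, across_subject_regression,
                           fisher_z_compare, fit_mixed_model, one_sample_t,
                           paired_t)


def test_one_sample_t_null_exact():
    r = one_sample_t([90.0] * 5)
    assert (r.statistic, r.p_value, r.effect_size) == (0.0, 1.0, 0.0)
    assert r.degenerate


def test_one_sample_t_textbook_oracle():
    vals = np.array([80.0, 100.0, 90.0, 85.0, 95.0])
    r = one_sample_t(vals)
    expected_t = (vals.mean() - 90) / (vals.std(ddof=1) / math.sqrt(5))
    assert r.statistic == pytest.approx(expected_t)
    assert r.df == 4


def test_cohens_d_equals_t_over_sqrt_n(rng):
    """d = t/sqrt(n) to machine precision; the printed convention check:
    t = -8.30, n = 28 gives d = -1.57."""
    for _ in range(20):
        v = rng.normal(85, 10, size=rng.integers(5, 60))
        r = one_sample_t(v)
        assert r.effect_size == pytest.approx(r.statistic / math.sqrt(r.n), rel=1e-12)
    assert -8.30 / math.sqrt(28) == pytest.approx(-1.57, abs=0.005)


def test_one_sample_t_calibration_under_uniform_guessing():
    """Under pure uniform responding the chance test rejects at ~alpha."""
    from ringmem.circular import angular_distance

    rng = np.random.default_rng(9)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        subj_means = [angular_distance(rng.uniform(0, 360, 100), 0.0).mean()
                      for _ in range(12)]
        rejections += one_sample_t(subj_means).p_value < 0.05
    assert 0.02 <= rejections / n_rep <= 0.09


@pytest.mark.parametrize("r1,n1,r2,n2,z_exp,p_exp", [
    (0.78, 29, 0.71, 28, 0.55, 0.58),
    (-0.75, 29, -0.42, 28, -1.87, 0.06),
])
def test_fisher_z_worked_examples(r1, n1, r2, n2, z_exp, p_exp):
    z, p = fisher_z_compare(r1, n1, r2, n2)
    assert z == pytest.approx(z_exp, abs=0.015)
    assert p == pytest.approx(p_exp, abs=0.01)


def test_fisher_z_antisymmetry_and_identity():
    z, p = fisher_z_compare(0.6, 30, 0.3, 25)
    z2, p2 = fisher_z_compare(0.3, 25, 0.6, 30)
    assert z2 == pytest.approx(-z) and p2 == pytest.approx(p)
    assert fisher_z_compare(0.4, 20, 0.4, 50)[0] == 0.0
    with pytest.raises(ValueError):
        fisher_z_compare(1.0, 20, 0.5, 20)


def test_regression_exact_fit_and_singularity(rng):
    df = pd.DataFrame({"x": rng.normal(size=30), "group": ["a", "b"] * 15})
    df["y"] = 2.5 * df.x - 1.0
    coefs = across_subject_regression(df, "y ~ x + group").set_index("term")
    assert coefs.loc["x", "estimate"] == pytest.approx(2.5, abs=1e-10)
    df["x2"] = 2 * df.x
    with pytest.raises(ValueError, match="collinear"):
        across_subject_regression(df, "y ~ x + x2")


def test_regression_recovers_generating_slope():
    """beta-hat within 2 SE of the generating slope in >= 90% of replicates."""
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 10, 40)
        y = 0.7 * x + rng.normal(0, 8, 40)
        c = across_subject_regression(
            pd.DataFrame({"x": x, "y": y}), "y ~ x").set_index("term")
        hits += abs(c.loc["x", "estimate"] - 0.7) <= 2 * c.loc["x", "se"]
    assert hits / n_rep >= 0.90


def _toy_anova_table():
    # 6 subjects (3 per group) x 2 phases, small integers for hand checking
    return pd.DataFrame({
        "subject_id": np.repeat([f"s{i}" for i in range(6)], 2),
        "group": np.repeat(["24h"] * 3 + ["1week"] * 3, 2),
        "phase": ["immediate", "delayed"] * 6,
        "divergence": [1.0, 2.0, 2.0, 3.0, 1.5, 2.5,
                       2.0, 5.0, 3.0, 6.0, 2.5, 5.5],
    })


def _hand_mixed_anova(df):
    """Independent SS decomposition for a balanced 2 (between) x 2 (within)."""
    wide = df.pivot_table(index=["subject_id", "group"], columns="phase",
                          values="divergence").reset_index()
    y = df.divergence
    grand = y.mean()
    subj_means = wide[["immediate", "delayed"]].mean(axis=1)
    group_of = wide.group
    n_per, k = len(wide) / 2, 2
    ss_group = sum(k * len(g) * (g.mean() - grand) ** 2
                   for _, g in subj_means.groupby(group_of))
    ss_subj_within = sum(k * (subj_means - subj_means.groupby(group_of).transform("mean")) ** 2)
    phase_means = df.groupby("phase").divergence.mean()
    ss_phase = sum(len(df) / 2 * (m - grand) ** 2 for m in phase_means)
    cell = df.groupby(["group", "phase"]).divergence.mean()
    ss_cells = sum(n_per * (cell[g][p] - grand) ** 2
                   for g in cell.index.levels[0] for p in cell[g].index)
    ss_inter = ss_cells - ss_group - ss_phase
    ss_total = sum((y - grand) ** 2)
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_phase - ss_inter
    df_bet, df_with = len(wide) - 2, len(wide) - 2
    out = {}
    out["group"] = (ss_group / 1) / (ss_subj_within / df_bet), ss_group / (ss_group + ss_subj_within)
    out["phase"] = (ss_phase / 1) / (ss_err_within / df_with), ss_phase / (ss_phase + ss_err_within)
    out["Interaction"] = (ss_inter / 1) / (ss_err_within / df_with), ss_inter / (ss_inter + ss_err_within)
    return out


def test_anova_2x2_against_hand_decomposition():
    df = _toy_anova_table()
    aov = anova_2x2(df).set_index("effect")
    oracle = _hand_mixed_anova(df)
    for effect, (f_exp, eta_exp) in oracle.items():
        assert aov.loc[effect, "F"] == pytest.approx(f_exp, rel=1e-6)
        assert aov.loc[effect, "partial_eta_sq"] == pytest.approx(eta_exp, rel=1e-6)


def test_anova_2x2_pure_crossover():
    df = _toy_anova_table()
    # construct a pure crossover: group x phase flips sign, no main effects
    rng = np.random.default_rng(1)
    sign = np.where(df.group == "24h", 1.0, -1.0)
    phase_sign = np.where(df.phase == "immediate", 1.0, -1.0)
    df = df.assign(divergence=5.0 + sign * phase_sign + rng.normal(0, 0.01, len(df)))
    aov = anova_2x2(df).set_index("effect")
    assert aov.loc["Interaction", "F"] > 1e3
    assert aov.loc["group", "F"] < 1.0
    assert aov.loc["phase", "F"] < 1.0


def test_anova_drops_incomplete_subjects():
    df = _toy_anova_table().iloc[:-1]  # s5 loses its delayed cell
    with pytest.warns(UserWarning, match="incomplete"):
        aov = anova_2x2(df)
    assert aov.set_index("effect").loc["group", "df2"] == 3


# ---------------------------------------------------------------------------
# mixed models


def _slope_data(seed, n_subj=12, n_trial=60, beta=0.3, slope_sd=0.1):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        b0 = rng.normal(0, 0.4)
        b1 = beta + rng.normal(0, slope_sd)
        x = rng.normal(0, 1, n_trial)
        y = b0 + b1 * x + rng.normal(0, 1, n_trial)
        rows.append(pd.DataFrame({"subject_id": f"s{s}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_mixed_model_recovers_known_slope():
    spec = ModelSpec("y", "x", random_slopes=["x"], standardize=[])
    hits = 0
    for seed in range(10):
        res = fit_mixed_model(_slope_data(seed), spec)
        t = res.table.set_index("term")
        est, se = t.loc["x", "estimate"], t.loc["x", "se"]
        hits += abs(est - 0.3) <= 2 * se
    assert hits >= 9


def test_mixed_model_df_rule_and_contrast():
    data = _slope_data(3)
    data["group"] = np.where(data.subject_id.isin([f"s{i}" for i in range(6)]),
                             "a", "b")
    spec = ModelSpec("y", "x * group", random_slopes=["x"], standardize=[])
    res = fit_mixed_model(data, spec)
    t = res.table.set_index("term")
    assert t.loc["group[T.b]", "df"] == res.n_subjects - 2  # between-subject
    assert t.loc["x", "df"] == res.n_subjects - 2  # random-sloped
    # contrast: slope within group b = x + x:group
    tr = res.contrast({"x": 1.0, "x:group[T.b]": 1.0})
    assert tr.effect_size == pytest.approx(
        t.loc["x", "estimate"] + t.loc["x:group[T.b]", "estimate"])
    with pytest.raises(KeyError):
        res.contrast({"nope": 1.0})


def test_mixed_model_t_invariant_to_affine_predictor_transform():
    data = _slope_data(5)
    spec = ModelSpec("y", "x", random_slopes=["x"], standardize=["x", "y"])
    t1 = fit_mixed_model(data, spec).table.set_index("term").loc["x", "t"]
    data2 = data.assign(x=3.0 * data.x + 7.0, y=0.5 * data.y - 2.0)
    t2 = fit_mixed_model(data2, spec).table.set_index("term").loc["x", "t"]
    assert t2 == pytest.approx(t1, rel=1e-4)


def test_mixed_model_null_slope_not_significant():
    res = fit_mixed_model(_slope_data(11, beta=0.0, slope_sd=0.0),
                          ModelSpec("y", "x", random_slopes=["x"], standardize=[]))
    assert res.table.set_index("term").loc["x", "p"] > 0.05
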
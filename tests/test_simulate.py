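import numpy as np
import pytest
from scipy import integrate

from ringmem.circular import angular_distance
from ringmem.design import DesignSpec, sample_cosine_locations
from ringmem.simulate import (GroupPreset, PhaseParams, VonMisesMixture,
                              default_presets, fit_mixture, mixture_pdf,
                              simulate_cohort, simulate_confidence,
                              simulate_response)


def params(w_epi, w_schema, w_guess, ke=10.0, ks=8.0):
    return PhaseParams(w_epi, w_schema, w_guess, ke, ks)


def test_weights_must_form_a_simplex():
    with pytest.raises(ValueError):
        params(0.5, 0.4, 0.2)
    with pytest.raises(ValueError):
        params(1.2, -0.1, -0.1)
    with pytest.raises(ValueError):
        PhaseParams(1, 0, 0, -1.0, 5.0)


def test_pure_episodic_degenerate_concentration(rng):
    resp = simulate_response(np.full(50, 123.0), 0.0, params(1, 0, 0, ke=1e6), rng)
    assert np.all(angular_distance(resp, 123.0) < 0.5)


def test_pure_guessing_hits_chance_level(rng):
    enc = np.full(100_000, 40.0)
    resp = simulate_response(enc, 200.0, params(0, 0, 1), rng)
    assert angular_distance(resp, enc).mean() == pytest.approx(90.0, abs=0.5)


def test_pure_schema_error_equals_consistency(rng):
    """With responses pinned to the center, trial error and trial
    schema-consistency are the same distance."""
    enc = rng.uniform(0, 360, size=200)
    resp = simulate_response(enc, 77.0, params(0, 1, 0, ks=1e8), rng)
    err = angular_distance(resp, enc)
    cons = angular_distance(enc, 77.0)
    assert err == pytest.approx(cons, abs=0.1)


def test_foils_draw_only_schema_or_guess(rng):
    enc = np.full(5000, np.nan)
    _, comp = simulate_response(enc, 10.0, params(0.6, 0.3, 0.1), rng,
                                return_components=True)
    assert set(comp) <= {"schema", "guess"}
    # proportional reallocation of the episodic weight: schema fraction 0.75
    assert np.mean(comp == "schema") == pytest.approx(0.75, abs=0.03)


def test_mixture_density_integrates_to_one():
    p = params(0.5, 0.3, 0.2, ke=12.0, ks=4.0)
    total, _ = integrate.quad(
        lambda x: mixture_pdf(np.rad2deg(x), 30.0, 210.0, p), 0, 2 * np.pi,
        limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_confidence_monotone_in_memory_strength(rng):
    """High-gain episodic draws earn rating 4; pure guessers miss old items;
    rated 3-4 trials are more precise than rated 1-2 trials."""
    precise = params(1, 0, 0, ke=50.0)
    comp = np.array(["epi"] * 2000)
    conf = simulate_confidence(comp, precise, confidence_gain=2.0, rng=rng)
    rated = conf[conf != "new"]
    assert np.mean(rated == "4") > 0.9

    guess = params(0, 0, 1)
    conf_g = simulate_confidence(np.array(["guess"] * 2000), guess, 1.0, rng)
    assert np.mean(conf_g == "new") > 0.1  # misses occur

    # cohort-level ordering: high-confidence responses are more precise
    mixed = params(0.5, 0.2, 0.3, ke=12.0, ks=6.0)
    enc = rng.uniform(0, 360, 20_000)
    resp, comps = simulate_response(enc, 90.0, mixed, rng, return_components=True)
    conf = simulate_confidence(comps, mixed, 1.0, rng)
    err = angular_distance(resp, enc)
    hi = np.isin(conf, ["3", "4"])
    lo = np.isin(conf, ["1", "2"])
    assert err[hi].mean() < err[lo].mean()


def test_cohort_shape_and_determinism():
    trials, designs, _ = simulate_cohort(n_subjects={"24h": 2, "1week": 2}, seed=3)
    per_subject = 360 + 120 + 168
    assert len(trials) == 4 * per_subject
    # ~3% missing responses among test trials only
    test = trials[trials.phase != "encode"]
    miss = test.response_angle_deg.isna().mean()
    assert 0.005 < miss < 0.08
    assert trials.response_angle_deg.notna()[trials.phase == "encode"].all()

    again, _, _ = simulate_cohort(n_subjects={"24h": 2, "1week": 2}, seed=3)
    assert trials.equals(again)
    other, _, _ = simulate_cohort(n_subjects={"24h": 2, "1week": 2}, seed=4)
    assert not trials.equals(other)


def test_default_presets_decay_asymmetry():
    presets = default_presets()
    for p in presets.values():
        assert p.epi_decay < p.schema_decay
    assert presets["1week"].epi_decay < presets["24h"].epi_decay
    with pytest.raises(ValueError):
        GroupPreset(group="x", epi_decay=0.0)


def test_delay_increases_error_more_with_longer_delay():
    """Sign check over replicate seeds: the 1-week cohort shows larger
    delayed-test error than the 24-h cohort."""
    wins = 0
    for seed in range(10):
        trials, designs, _ = simulate_cohort(
            n_subjects={"24h": 6, "1week": 6}, seed=100 + seed,
            design_kwargs={"n_encode_per_category": 20, "n_foils_per_category": 4},
        )
        t = trials[(trials.phase == "delayed") & (trials.item_status == "old")
                   & trials.response_angle_deg.notna()]
        err = angular_distance(t.encoded_angle_deg.to_numpy(),
                               t.response_angle_deg.to_numpy())
        means = {g: err[(t.group == g).to_numpy()].mean() for g in ("24h", "1week")}
        wins += means["1week"] > means["24h"]
    assert wins >= 8


# ---------------------------------------------------------------------------
# mixture fitting


def _simulate_subject(true: PhaseParams, n, rng, center=300.0):
    enc = sample_cosine_locations(center, n, rng)
    resp = simulate_response(enc, center, true, rng)
    return resp, enc, center


def test_pure_component_recovery(rng):
    true = params(1, 0, 0, ke=50.0)
    resp, enc, center = _simulate_subject(true, 120, rng)
    fit = fit_mixture(resp, enc, center)
    assert fit.w_epi >= 0.95


def test_fit_requires_enough_trials(rng):
    with pytest.raises(ValueError):
        fit_mixture([1.0, 2.0], [1.0, 2.0], 0.0)
    with pytest.warns(UserWarning):
        fit_mixture(rng.uniform(0, 360, 10), rng.uniform(0, 360, 10), 0.0)


def test_degenerate_input_flagged(rng):
    enc = rng.uniform(0, 360, 60)
    fit = fit_mixture(np.full(60, 42.0), enc, 0.0)
    assert fit.degenerate


def test_cohort_mean_weight_recovery():
    """EM recovers the generating weights on average over 30 subjects."""
    true = params(0.6, 0.25, 0.15, ke=10.0, ks=8.0)
    rng = np.random.default_rng(202)
    weights = []
    for _ in range(30):
        resp, enc, center = _simulate_subject(true, 120, rng,
                                              center=rng.uniform(0, 360))
        weights.append(fit_mixture(resp, enc, center).weights)
    err = np.abs(np.mean(weights, axis=0) - true.weights)
    assert np.all(err < 0.05)


def test_fitted_likelihood_dominates_generating_parameters():
    true = params(0.5, 0.3, 0.2, ke=15.0, ks=5.0)
    rng = np.random.default_rng(77)
    resp, enc, center = _simulate_subject(true, 200, rng)
    fitter = VonMisesMixture()
    fit = fitter.fit(resp, enc, center)
    ll_true = fitter.log_likelihood(true, resp, enc, center)
    assert fit.log_likelihood >= ll_true - 1e-6
    assert fit.converged
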
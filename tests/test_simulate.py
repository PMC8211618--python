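"""Generative-model behaviour: first-passage statistics, serial bottleneck
composition, parallel capacity sharing, experiment assembly."""

import numpy as np
import pytest

from prpddm.design import preset, DesignConfig
from prpddm.simulate import (GenerativeParams, PopulationSds, default_population,
                             sample_subject_params, serial_compose, simulate_experiment,
                             simulate_fpt, simulate_fpt_batch, simulate_trial_parallel,
                             simulate_trial_serial, _simulate_trials)
from prpddm.wfpt import DDMParams, closed_forms


@pytest.mark.parametrize("a,v", [(1.5, 2.0), (1.0, 0.0), (2.0, -1.0)])
def test_fpt_matches_closed_forms(a, v):
    """Absorption probability and mean first-passage time match the analytic
    values for the unbiased start, within 3 Monte-Carlo standard errors."""
    rng = np.random.default_rng(3)
    n = 6000
    times_ms, upper, flagged = simulate_fpt_batch(a, v, n, rng)
    assert not flagged.any()
    p_true, mean_true = closed_forms(DDMParams(a=a, v=v, t0=0.0))
    se_p = np.sqrt(p_true * (1 - p_true) / n)
    assert abs(upper.mean() - p_true) < 3 * se_p + 1e-12
    se_m = times_ms.std() / np.sqrt(n)
    assert abs(times_ms.mean() - mean_true * 1000) < 3 * se_m


def test_fpt_single_draw_interface():
    rng = np.random.default_rng(0)
    t, up = simulate_fpt(1.5, 2.0, rng)
    assert t > 0 and isinstance(up, bool)
    with pytest.raises(ValueError):
        simulate_fpt(-1.0, 2.0, rng)


def test_serial_compose_bottleneck_arithmetic():
    """Deterministic stage composition: slack loads onto RT2 at short SOA and
    vanishes once the SOA outlasts the Task-1 decision."""
    p, _ = default_population("serial")
    D, d2 = 300.0, 250.0
    # soa = 0 and encode_1 + D > encode_2: Task 2 waits for Task 1
    rt1, rt2 = serial_compose(p, 0.0, D, d2)
    assert rt1 == p.encode_1 + D + p.motor_1
    assert rt2 == p.encode_1 + D + d2 + p.motor_2
    # zero-slack regime: soa >= encode_1 + D - encode_2
    soa = p.encode_1 + D - p.encode_2 + 50.0
    _, rt2_free = serial_compose(p, soa, D, d2)
    assert rt2_free == p.encode_2 + d2 + p.motor_2


def test_negative_soa_rejected():
    p, _ = default_population("serial")
    with pytest.raises(ValueError, match="negative"):
        simulate_trial_serial(p, -50.0, np.random.default_rng(0))
    q, _ = default_population("parallel")
    with pytest.raises(ValueError, match="negative"):
        simulate_trial_parallel(q, -50.0, np.random.default_rng(0))


def test_mode_mismatch_rejected():
    p, _ = default_population("serial")
    with pytest.raises(ValueError):
        simulate_trial_parallel(p, 100.0, np.random.default_rng(0))


def test_prp_signature_slope():
    """Mean RT2 falls ~1 ms per ms of SOA in the slack-dominated regime and
    flattens at the longest SOA (the PRP effect).

    Stage parameters put Task-2 encoding well inside Task-1's processing so
    the bottleneck blocks on every trial at the short SOAs (encode_1 >
    soa + encode_2 is guaranteed by encode_1 - encode_2 = 150 ms >= soa).
    """
    base, _ = default_population("serial")
    p = GenerativeParams(**{**base.to_dict(), "encode_1": 250.0, "encode_2": 100.0})
    rng = np.random.default_rng(11)
    n = 4000
    means = {}
    for soa in (0.0, 100.0, 900.0, 1100.0):
        _, rt2, _, _ = _simulate_trials(p, np.full(n, soa), rng, 1e-4, 10.0)
        means[soa] = rt2.mean()
    slope_short = (means[100.0] - means[0.0]) / 100.0
    slope_long = (means[1100.0] - means[900.0]) / 200.0
    assert abs(slope_short + 1.0) < 0.12
    assert abs(slope_long) < 0.12


def test_parallel_vs_serial_contrast_at_short_soa():
    """At the shortest SOA capacity sharing slows Task 1 and speeds Task 2
    relative to the bottleneck account with identical stage parameters."""
    ser, _ = default_population("serial")
    par, _ = default_population("parallel")
    rng = np.random.default_rng(21)
    n = 4000
    soas = np.full(n, 100.0)
    rt1_s, rt2_s, _, _ = _simulate_trials(ser, soas, rng, 1e-4, 10.0)
    rt1_p, rt2_p, _, _ = _simulate_trials(par, soas, rng, 1e-4, 10.0)
    assert rt1_p.mean() > rt1_s.mean() + 10
    assert rt2_p.mean() < rt2_s.mean() - 10


def test_parallel_no_overlap_matches_serial_at_long_soa():
    """With an SOA far beyond any Task-1 completion there is no overlap, so
    both generators produce the same (isolated-task) RT distributions."""
    ser, _ = default_population("serial")
    par, _ = default_population("parallel")
    rng = np.random.default_rng(31)
    n = 3000
    soas = np.full(n, 4000.0)
    rt1_s, rt2_s, _, _ = _simulate_trials(ser, soas, rng, 1e-4, 10.0)
    rt1_p, rt2_p, _, _ = _simulate_trials(par, soas, rng, 1e-4, 10.0)
    for a, b in ((rt1_s, rt1_p), (rt2_s, rt2_p)):
        se = np.hypot(a.std() / np.sqrt(n), b.std() / np.sqrt(n))
        assert abs(a.mean() - b.mean()) < 3.5 * se


def test_extreme_share_postpones_task2():
    """share_1 near 1 starves Task 2 during overlap, pushing RT2 toward the
    serial postponement pattern."""
    base, _ = default_population("parallel")
    greedy = GenerativeParams(**{**base.to_dict(), "share_1": 0.95})
    fair = GenerativeParams(**{**base.to_dict(), "share_1": 0.3})
    soas = np.full(4000, 100.0)
    _, rt2_g, _, c2_g = _simulate_trials(greedy, soas, np.random.default_rng(41), 1e-4, 10.0)
    _, rt2_f, _, _ = _simulate_trials(fair, soas, np.random.default_rng(41), 1e-4, 10.0)
    assert rt2_g.mean() > rt2_f.mean() + 10
    # starving Task 2 of capacity also costs it accuracy
    assert c2_g.mean() < 0.95


def test_sample_subject_params():
    means, _ = default_population("serial")
    rng = np.random.default_rng(5)
    # zero spread -> exact means
    zero = PopulationSds(0.0, 0.0, 0.0, 0.0, 0.0)
    assert sample_subject_params(means, zero, rng) == means
    # determinism under a fixed seed
    sds = PopulationSds()
    p1 = sample_subject_params(means, sds, np.random.default_rng(9))
    p2 = sample_subject_params(means, sds, np.random.default_rng(9))
    assert p1 == p2
    # law of large numbers for the boundary separation
    draws = np.array([sample_subject_params(means, sds, rng).a_1 for _ in range(4000)])
    se = sds.a / np.sqrt(len(draws))
    assert abs(draws.mean() - means.a_1) < 4 * se
    # mean outside the truncation bounds is rejected outright
    bad = GenerativeParams(**{**means.to_dict(), "a_1": 0.05})
    with pytest.raises(ValueError, match="bounds"):
        sample_subject_params(bad, sds, rng)


def test_simulate_experiment_geometry_and_determinism():
    configs = {c: preset("exp3", c, n_subjects_per_condition=2, n_blocks=2,
                         trials_per_block=40) for c in ("SF", "LF")}
    pops = {c: default_population("serial") for c in ("SF", "LF")}
    trials, sidecar = simulate_experiment(configs, pops, seed=77)
    assert len(trials) == 4 * 80
    per_subject = trials.groupby("subject_id").size()
    assert (per_subject == 80).all()
    # no-go bookkeeping: exact count, undefined rt2, correct2 true
    nogo = trials[trials["is_nogo"]]
    assert len(nogo) == int(0.175 * len(trials))
    assert nogo["rt2_ms"].isna().all()
    assert nogo["correct2"].all()
    assert trials.loc[~trials["is_nogo"], "rt2_ms"].notna().all()
    assert (trials["rt1_ms"] > 0).all()
    assert set(sidecar) == set(trials["subject_id"].unique())
    # full determinism under the seed
    trials2, _ = simulate_experiment(configs, pops, seed=77)
    assert trials.equals(trials2)
    # distinct subjects receive distinct substreams
    g = trials.groupby("subject_id")["rt1_ms"].mean()
    assert g.nunique() == len(g)


def test_serial_rt1_invariant_across_soa(serial_small):
    """The bottleneck account has no SOA -> RT1 pathway: within a subject,
    RT1 cell means differ across SOA levels only by sampling noise.

    (Centering within subjects is required because the SF/LF groups have
    different SOA compositions and different sampled subjects.)"""
    trials, _ = serial_small
    cell = trials.groupby(["subject_id", "soa_ms"])["rt1_ms"].mean()
    centered = cell - cell.groupby("subject_id").transform("mean")
    by_soa = centered.groupby("soa_ms").mean()
    assert by_soa.max() - by_soa.min() < 15  # ms; rare cells have ~40 trials


def test_iri_floor_option():
    configs = {c: preset("exp1", c, n_subjects_per_condition=1, n_blocks=1,
                         trials_per_block=40) for c in ("SF", "LF")}
    pops = {c: default_population("serial") for c in ("SF", "LF")}
    trials, _ = simulate_experiment(configs, pops, seed=13, iri_floor=100.0)
    go = ~trials["is_nogo"]
    iri = trials.loc[go, "soa_ms"] + trials.loc[go, "rt2_ms"] - trials.loc[go, "rt1_ms"]
    assert (iri >= 100.0 - 1e-9).all()
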
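"""Mixed-ANOVA correctness (hand-computed sums of squares + permutation
oracle) and t-test utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prpddm.rt_stats import bonferroni, mixed_anova_2x3, paired_t, welch_t


def _make_cells(values: dict[str, np.ndarray], soas=(100.0, 300.0, 800.0)) -> pd.DataFrame:
    """Build a cell-means table from {subject: [m_short, m_med, m_long]}
    with condition taken from the subject-id prefix."""
    rows = []
    for sid, vals in values.items():
        for soa, v in zip(soas, vals):
            rows.append({"subject_id": sid, "condition": sid[:2], "soa_ms": soa,
                         "task": 1, "mean_rt": float(v), "error_rate": 0.0,
                         "n_retained": 10, "empty_cell": False})
    return pd.DataFrame(rows)


def _hand_mixed_anova(data: np.ndarray, groups: np.ndarray):
    """Textbook balanced mixed-ANOVA sums of squares.

    data: (subjects, b within levels); groups: subject group index (0/1).
    Returns dict of F statistics and the SS partition.
    """
    n_subj, b = data.shape
    a_levels = np.unique(groups)
    a = len(a_levels)
    n = n_subj // a
    grand = data.mean()
    subj_means = data.mean(axis=1)
    ss_total = ((data - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_A = sum(n * b * (data[groups == g].mean() - grand) ** 2 for g in a_levels)
    ss_subj_within = ss_between_subj - ss_A
    ss_B = n_subj * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_AB = 0.0
    for g in a_levels:
        cell = data[groups == g].mean(axis=0)
        ss_AB += n * ((cell - data[groups == g].mean() - data.mean(axis=0) + grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_B - ss_AB
    F_A = (ss_A / (a - 1)) / (ss_subj_within / (a * (n - 1)))
    F_B = (ss_B / (b - 1)) / (ss_err / (a * (n - 1) * (b - 1)))
    F_AB = (ss_AB / ((a - 1) * (b - 1))) / (ss_err / (a * (n - 1) * (b - 1)))
    return {"F_A": F_A, "F_B": F_B, "F_AB": F_AB,
            "partition": (ss_A, ss_subj_within, ss_B, ss_AB, ss_err, ss_total)}


@pytest.fixture()
def toy_design():
    rng = np.random.default_rng(3)
    data = np.empty((8, 3))
    groups = np.repeat([0, 1], 4)
    for i in range(8):
        base = 600 + rng.normal(0, 40)
        effect = np.array([0, -30, -60]) if groups[i] else np.array([0, 0, 0])
        data[i] = base + effect + rng.normal(0, 15, 3)
    sids = [f"SF{i}" for i in range(4)] + [f"LF{i}" for i in range(4)]
    cells = _make_cells({sid: data[i] for i, sid in enumerate(sids)})
    return data, groups, cells


def test_f_statistics_match_hand_computation(toy_design):
    data, groups, cells = toy_design
    hand = _hand_mixed_anova(data, groups)
    tab = mixed_anova_2x3(cells)
    assert tab.effect("condition")["F"] == pytest.approx(hand["F_A"], rel=1e-6)
    assert tab.effect("soa")["F"] == pytest.approx(hand["F_B"], rel=1e-6)
    assert tab.effect("condition x soa")["F"] == pytest.approx(hand["F_AB"], rel=1e-6)


def test_sums_of_squares_partition_exactly(toy_design):
    data, groups, _ = toy_design
    ss_A, ss_sw, ss_B, ss_AB, ss_err, ss_total = _hand_mixed_anova(data, groups)["partition"]
    assert ss_A + ss_sw + ss_B + ss_AB + ss_err == pytest.approx(ss_total, rel=1e-12)
    assert min(ss_A, ss_sw, ss_B, ss_AB, ss_err) >= 0


def test_between_effect_agrees_with_permutation_oracle(toy_design):
    """Exact label-permutation p for the condition effect tracks the
    parametric p on a small normal dataset."""
    data, groups, cells = toy_design
    tab = mixed_anova_2x3(cells)
    F_obs = tab.effect("condition")["F"]
    perm_F = []
    for idx in itertools.combinations(range(8), 4):
        g = np.ones(8, dtype=int)
        g[list(idx)] = 0
        perm_F.append(_hand_mixed_anova(data, g)["F_A"])
    p_perm = np.mean(np.asarray(perm_F) >= F_obs - 1e-12)
    assert abs(p_perm - tab.effect("condition")["p"]) < 0.2


def test_no_effect_by_construction_gives_null_interaction():
    """Both conditions share one SOA profile; the interaction F collapses."""
    rng = np.random.default_rng(9)
    profile = np.array([600.0, 580.0, 560.0])
    values = {}
    for c in ("SF", "LF"):
        for i in range(6):
            values[f"{c}{i}"] = profile + rng.normal(0, 50) + rng.normal(0, 1.0, 3)
    tab = mixed_anova_2x3(_make_cells(values))
    inter = tab.effect("condition x soa")
    assert inter["F"] < 2.5
    assert inter["p"] > 0.1


def test_gg_correction_bookkeeping(toy_design):
    """Epsilon in (0.5, 1]; the corrected p reproduces the F tail at
    epsilon-shrunk dfs, and epsilon = 1 would recover the uncorrected p."""
    _, _, cells = toy_design
    tab = mixed_anova_2x3(cells)
    soa = tab.effect("soa")
    assert 0.5 < soa["epsilon"] <= 1.0 + 1e-9
    if soa["gg_applied"]:
        expected = stats.f.sf(soa["F"], soa["epsilon"] * soa["df_num"],
                              soa["epsilon"] * soa["df_den"])
        assert soa["p"] == pytest.approx(expected, rel=1e-9)
    else:
        assert soa["p"] == pytest.approx(soa["p_uncorrected"], rel=1e-12)
    assert stats.f.sf(soa["F"], 1.0 * soa["df_num"], 1.0 * soa["df_den"]) == \
        pytest.approx(soa["p_uncorrected"], rel=1e-9)
    assert 0 <= soa["eta_p_sq"] <= 1


def test_missing_cells_raise(toy_design):
    _, _, cells = toy_design
    broken = cells[~((cells["subject_id"] == "SF0") & (cells["soa_ms"] == 300.0))]
    with pytest.raises(ValueError, match="SF0"):
        mixed_anova_2x3(broken)


def test_prp_main_effect_on_synthetic_data(serial_small):
    """The SOA main effect on RT2 is overwhelming in serial-mode data."""
    from prpddm.preprocess import aggregate_cells, exclude_trials

    trials, _ = serial_small
    retained, _ = exclude_trials(trials)
    cells = aggregate_cells(retained, trials)
    tab = mixed_anova_2x3(cells, dv="mean_rt", task=2)
    soa = tab.effect("soa")
    assert soa["F"] > 20
    assert soa["p"] < 0.001
    assert soa["eta_p_sq"] > 0.5


def test_welch_df_matches_hand_formula():
    a = np.array([5.1, 5.4, 4.9, 5.3, 5.0])
    b = np.array([6.2, 6.9, 5.8, 7.1, 6.0])
    res = welch_t(a, b)
    va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
    df_hand = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
    assert res.df == pytest.approx(df_hand, rel=1e-10)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert res.statistic == pytest.approx(t_hand, rel=1e-10)
    assert res.flavor == "welch"


def test_degenerate_t_tests():
    x = np.array([1.0, 2.0, 3.0])
    res = welch_t(x, x)
    assert res.statistic == 0.0 and res.p_raw == pytest.approx(1.0)
    # constant positive differences with tiny jitter: essentially certain
    d = 5.0 + np.array([1e-6, -1e-6, 2e-6, -2e-6])
    assert paired_t(d).p_raw < 1e-10
    assert paired_t(d).df == 3
    with pytest.raises(ValueError, match="variance"):
        welch_t(np.ones(3), np.ones(3))
    with pytest.raises(ValueError, match="variance"):
        paired_t(np.full(4, 2.0))


def test_bonferroni_adjustment():
    r = welch_t(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 6]))
    out = bonferroni([r, r, r])
    assert all(x.p_adjusted == pytest.approx(min(1.0, 3 * x.p_raw)) for x in out)
    assert all(x.m_comparisons == 3 for x in out)
    out5 = bonferroni([r], m=5)
    assert out5[0].p_adjusted == pytest.approx(min(1.0, 5 * r.p_raw))
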
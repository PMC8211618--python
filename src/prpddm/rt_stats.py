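"""Conventional inference: 2 (condition) x 3 (SOA) mixed ANOVA and t tests.

The ANOVA treats SOA-frequency condition (SF vs LF) as a between-subjects
factor and SOA as a within-subjects factor, reporting partial eta squared,
Mauchly's sphericity test, and — when sphericity is rejected at alpha = .05 —
Greenhouse-Geisser-corrected p values (epsilon applied to both numerator and
denominator df; the uncorrected df are kept for display).  The same epsilon
corrects both within-factor effects (SOA and the interaction), as they share
the within-subject error covariance.

Between-condition contrasts use Welch's unequal-variance t test
(Welch-Satterthwaite fractional df); within-subject contrasts use paired t
tests; families of comparisons are Bonferroni-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = ["AnovaTable", "TTestResult", "mixed_anova_2x3", "welch_t", "paired_t", "bonferroni"]

_ALPHA_SPHERICITY = 0.05


@dataclass(frozen=True)
class AnovaTable:
    """Tidy 2x3 mixed ANOVA result; one row per effect in ``table``.

    Columns: effect, F, df_num, df_den, p_uncorrected, p (GG-corrected where
    sphericity was rejected, else uncorrected), eta_p_sq, epsilon, mauchly_p.
    """

    dv: str
    task: int
    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]

    def report(self) -> str:
        """Human-readable lines in the field's reporting style."""
        lines = [f"ANOVA, task {self.task}, dv={self.dv}"]
        for _, r in self.table.iterrows():
            s = (f"  {r['effect']}: F({r['df_num']:g}, {r['df_den']:g}) = {r['F']:.2f}, "
                 f"p = {r['p']:.3f}, eta_p^2 = {r['eta_p_sq']:.2f}")
            if np.isfinite(r["epsilon"]):
                s += f", eps = {r['epsilon']:.3f}"
            lines.append(s)
        return "\n".join(lines)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_raw: float
    flavor: str  # 'welch' or 'paired'
    p_adjusted: float | None = None
    m_comparisons: int | None = None

    def report(self) -> str:
        s = f"t({self.df:.2f}) = {self.statistic:.2f}, p = {self.p_raw:.3f} ({self.flavor})"
        if self.p_adjusted is not None:
            s += f", p_bonf = {self.p_adjusted:.3f} (m = {self.m_comparisons})"
        return s


def mixed_anova_2x3(cells: pd.DataFrame, dv: str = "mean_rt", task: int = 1) -> AnovaTable:
    """2x3 mixed ANOVA on per-subject cell means of one task.

    ``cells`` is the long table from :func:`prpddm.preprocess.aggregate_cells`
    (columns subject_id, condition, soa_ms, task, mean_rt, error_rate).
    Every subject must contribute all three SOA cells.
    """
    if dv not in ("mean_rt", "error_rate"):
        raise ValueError(f"dv must be 'mean_rt' or 'error_rate', got {dv!r}")
    data = cells[cells["task"] == task].copy()
    if data.empty:
        raise ValueError(f"no cells for task {task}")
    counts = data.groupby("subject_id")["soa_ms"].nunique()
    n_levels = data["soa_ms"].nunique()
    bad = counts.index[counts != n_levels].tolist()
    if data[dv].isna().any():
        bad = sorted(set(bad) | set(data.loc[data[dv].isna(), "subject_id"]))
    if bad:
        raise ValueError(f"subjects with missing SOA cells for dv={dv!r}: {bad}")

    res = pg.mixed_anova(data=data, dv=dv, within="soa_ms", subject="subject_id",
                         between="condition", correction=True)
    within = res[res["Source"] == "soa_ms"].iloc[0]
    eps = float(within["eps"])
    mauchly_p = float(within["p_spher"])
    correct = mauchly_p < _ALPHA_SPHERICITY

    rows = []
    for src, effect in (("condition", "condition"), ("soa_ms", "soa"),
                        ("Interaction", "condition x soa")):
        r = res[res["Source"] == src].iloc[0]
        F, d1, d2 = float(r["F"]), float(r["DF1"]), float(r["DF2"])
        is_within = src != "condition"
        p_unc = float(r["p_unc"])
        if is_within and correct:
            p = float(stats.f.sf(F, eps * d1, eps * d2))
        else:
            p = p_unc
        rows.append({
            "effect": effect, "F": F, "df_num": d1, "df_den": d2,
            "p_uncorrected": p_unc, "p": p,
            "eta_p_sq": float(r["np2"]),
            "epsilon": eps if is_within else np.nan,
            "mauchly_p": mauchly_p if is_within else np.nan,
            "gg_applied": bool(is_within and correct),
        })
    return AnovaTable(dv=dv, task=task, table=pd.DataFrame(rows))


def welch_t(group_a, group_b) -> TTestResult:
    """Welch's unequal-variance t test for between-condition contrasts."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch")


def paired_t(diffs) -> TTestResult:
    """One-sample t test on paired differences (df = n - 1)."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two paired differences")
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of differences; t test undefined")
    res = stats.ttest_1samp(d, 0.0)
    return TTestResult(float(res.statistic), float(len(d) - 1), float(res.pvalue), "paired")


def bonferroni(results: list[TTestResult], m: int | None = None) -> list[TTestResult]:
    """Bonferroni-adjust a family of tests; m defaults to the family size."""
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("m must be at least 1")
    return [replace(r, p_adjusted=min(1.0, m * r.p_raw), m_comparisons=m) for r in results]
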
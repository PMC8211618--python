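"""Trial exclusion and per-cell aggregation for dual-task RT analyses.

The exclusion cascade, applied in this fixed order:

1. **errors** — trials with an incorrect response (by default on either task);
2. **RT window** — trials where rt1 or rt2 (go trials) falls outside
   [200, 2000] ms;
3. **no-go** — optionally, Task-2 no-go trials;
4. **IRI** — optionally, trials whose inter-response interval
   ``(soa + rt2) - rt1`` falls below a floor.

Error rates are aggregated on the pre-RT-window set so that fast or slow
errors still count as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .simulate import TRIAL_COLUMNS

__all__ = ["ExclusionReport", "compute_iri", "exclude_trials", "aggregate_cells"]


@dataclass(frozen=True)
class ExclusionReport:
    """Book-keeping of one exclusion pass; counts reconcile exactly."""

    n_input: int
    n_error_excluded: int
    n_rt_window_excluded: int
    n_nogo_excluded: int
    n_short_iri_flagged: int
    n_output: int

    @property
    def fraction_removed(self) -> float:
        return 0.0 if self.n_input == 0 else (self.n_input - self.n_output) / self.n_input

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_removed"] = self.fraction_removed
        return d


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    bad_rt1 = trials.index[~(trials["rt1_ms"] > 0)]
    if len(bad_rt1):
        raise ValueError(f"non-positive or missing rt1 at rows {list(bad_rt1[:5])}")
    go = ~trials["is_nogo"].astype(bool)
    bad_rt2 = trials.index[go & ~(trials["rt2_ms"] > 0)]
    if len(bad_rt2):
        raise ValueError(f"non-positive or missing rt2 on go trials at rows {list(bad_rt2[:5])}")
    return trials


def compute_iri(trials: pd.DataFrame) -> pd.Series:
    """Inter-response interval (ms): ``(soa + rt2) - rt1``.

    Defined for go trials only; raises on no-go rows.
    """
    if trials["is_nogo"].astype(bool).any():
        raise ValueError("IRI is undefined on no-go trials; filter them out first")
    return trials["soa_ms"] + trials["rt2_ms"] - trials["rt1_ms"]


def exclude_trials(trials: pd.DataFrame, *, rt_min: float = 200.0, rt_max: float = 2000.0,
                   drop_nogo: bool = False, iri_floor: float | None = None,
                   error_policy: str = "either") -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade; returns (retained trials, report).

    error_policy controls step 1: ``"either"`` drops trials with an error on
    either task (RT analyses); ``"task1"``/``"task2"`` drop only errors of the
    *other* task, keeping the named task's error trials for accuracy-coded
    model fitting; ``"none"`` skips error exclusion.
    """
    if error_policy not in ("either", "task1", "task2", "none"):
        raise ValueError(f"unknown error_policy {error_policy!r}")
    n_input = len(trials)
    if n_input == 0:
        return trials.copy(), ExclusionReport(0, 0, 0, 0, 0, 0)
    trials = _validate(trials)

    df = trials.copy()
    go = ~df["is_nogo"].astype(bool)

    if error_policy == "either":
        err = ~df["correct1"].astype(bool) | (go & ~df["correct2"].astype(bool))
    elif error_policy == "task1":  # fit Task 1: keep its errors, drop Task-2 errors
        err = go & ~df["correct2"].astype(bool)
    elif error_policy == "task2":
        err = ~df["correct1"].astype(bool)
    else:
        err = pd.Series(False, index=df.index)
    n_err = int(err.sum())
    df = df[~err]

    go = ~df["is_nogo"].astype(bool)
    out1 = (df["rt1_ms"] < rt_min) | (df["rt1_ms"] > rt_max)
    out2 = go & ((df["rt2_ms"] < rt_min) | (df["rt2_ms"] > rt_max))
    window = out1 | out2
    n_window = int(window.sum())
    df = df[~window]

    n_nogo = 0
    if drop_nogo:
        nogo = df["is_nogo"].astype(bool)
        n_nogo = int(nogo.sum())
        df = df[~nogo]

    n_iri = 0
    if iri_floor is not None:
        go = ~df["is_nogo"].astype(bool)
        iri = df.loc[go, "soa_ms"] + df.loc[go, "rt2_ms"] - df.loc[go, "rt1_ms"]
        short = iri.index[iri < iri_floor]
        n_iri = len(short)
        df = df.drop(index=short)

    report = ExclusionReport(n_input, n_err, n_window, n_nogo, n_iri, len(df))
    assert report.n_output == n_input - n_err - n_window - n_nogo - n_iri
    return df.reset_index(drop=True), report


def aggregate_cells(retained: pd.DataFrame, all_trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x SOA x task cell means, long format.

    RT means come from the retained trials; error rates from the full input
    set minus no-go rows (errors must count even when their RT was excluded).
    Cells with no retained trials are kept with NaN mean and flagged.
    """
    if retained.empty:
        raise ValueError("no retained trials to aggregate")
    base = all_trials[~all_trials["is_nogo"].astype(bool)]
    ret_go = retained[~retained["is_nogo"].astype(bool)]
    meta = all_trials[["subject_id", "condition"]].drop_duplicates()
    soas = np.sort(all_trials["soa_ms"].unique())
    # full subject x SOA grid so empty cells surface instead of vanishing
    grid = meta.merge(pd.DataFrame({"soa_ms": soas}), how="cross")

    keys = ["subject_id", "soa_ms"]
    rt = ret_go.groupby(keys).agg(
        rt1=("rt1_ms", "mean"), rt2=("rt2_ms", "mean"), n_retained=("rt1_ms", "size"))
    err = base.groupby(keys).agg(err1=("correct1", lambda c: float((~c.astype(bool)).mean())),
                                 err2=("correct2", lambda c: float((~c.astype(bool)).mean())))
    wide = grid.merge(rt, on=keys, how="left").merge(err, on=keys, how="left")
    wide["n_retained"] = wide["n_retained"].fillna(0).astype(int)

    frames = []
    for task in (1, 2):
        frames.append(pd.DataFrame({
            "subject_id": wide["subject_id"],
            "condition": wide["condition"],
            "soa_ms": wide["soa_ms"],
            "task": task,
            "mean_rt": wide[f"rt{task}"],
            "error_rate": wide[f"err{task}"],
            "n_retained": wide["n_retained"],
            "empty_cell": wide["n_retained"] == 0,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "soa_ms", "task"], kind="stable").reset_index(drop=True)
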
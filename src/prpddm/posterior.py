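"""Decision layer on posterior draws: posterior-proportion P and aggregation.

Within one joint model, two parameter posteriors are compared by the
proportion P of draws for which one exceeds the other; P > 0.950 counts as a
substantial difference.  Comparisons are iteration-paired by default (nodes
of one joint posterior are correlated through the shared data); a pooled
all-pairs variant is available for sensitivity checks.  Ties — possible in
finite-precision persisted draws — count against the strict inequality.

Across models (e.g. Task 1 vs Task 2), posteriors are first aggregated to
per-participant posterior means and then compared with frequentist t tests
(paired within subjects, Welch between conditions), Bonferroni-adjusted per
parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hier import PosteriorDraws

__all__ = ["ComparisonResult", "bayesian_p", "diff_of_diffs", "participant_posterior_means",
           "P_CRITERION"]

P_CRITERION = 0.950


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one posterior comparison against the 0.950 criterion."""

    kind: str  # 'bayesian_P'
    P: float
    direction: str  # 'greater' or 'less': tested relation of a vs b
    substantial: bool
    provenance: str
    p_tie: float = 0.0

    def report(self) -> str:
        mark = "substantial" if self.substantial else "not substantial"
        return f"P({self.provenance} {self.direction}) = {self.P:.3f} [{mark}]"


def _as_draws(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValueError("empty draw vector")
    return arr


def bayesian_p(draws_a, draws_b, direction: str = "greater", *,
               paired: bool = True, provenance: str = "a vs b") -> ComparisonResult:
    """Proportion of posterior mass where ``a`` exceeds (or falls below) ``b``.

    With ``paired=True`` (default) draws are compared iteration by iteration
    and must have equal length; ``paired=False`` compares all cross pairs.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = _as_draws(draws_a)
    b = _as_draws(draws_b)
    if paired:
        if len(a) != len(b):
            raise ValueError(f"paired comparison needs equal draw counts ({len(a)} vs {len(b)})")
        diff = a - b
        p_greater = float(np.mean(diff > 0))
        p_tie = float(np.mean(diff == 0))
    else:
        comp = a[:, None] - b[None, :]
        p_greater = float(np.mean(comp > 0))
        p_tie = float(np.mean(comp == 0))
    P = p_greater if direction == "greater" else 1.0 - p_greater - p_tie
    return ComparisonResult(kind="bayesian_P", P=P, direction=direction,
                            substantial=P > P_CRITERION, provenance=provenance, p_tie=p_tie)


def diff_of_diffs(short_a, long_a, short_b, long_b, direction: str = "less", *,
                  provenance: str = "(shortA-longA) vs (shortB-longB)") -> ComparisonResult:
    """Compare SOA effects between groups within one joint posterior.

    Forms the iteration-paired difference distributions (short - long) in each
    group and tests whether group A's difference is smaller/larger than group
    B's.
    """
    sa, la, sb, lb = map(_as_draws, (short_a, long_a, short_b, long_b))
    if not (len(sa) == len(la) == len(sb) == len(lb)):
        raise ValueError("all four nodes must come from one joint posterior (equal draws)")
    return bayesian_p(sa - la, sb - lb, direction=direction, paired=True,
                      provenance=provenance)


def participant_posterior_means(post: PosteriorDraws) -> pd.DataFrame:
    """Per-subject posterior-mean point estimates, long format.

    Columns: subject_id, condition, parameter (a / v / t0), cell (short /
    long; empty for a), estimate.  Chain order does not matter (means over
    all retained draws).
    """
    rows = []
    for sid, cond in sorted(post.subjects.items()):
        a_node = f"a[{sid}]"
        if a_node not in post.draws:
            raise ValueError(f"missing subject-level node {a_node}")
        rows.append({"subject_id": sid, "condition": cond, "parameter": "a",
                     "cell": "", "estimate": float(post.stacked(a_node).mean())})
        for par in ("v", "t0"):
            for cell in ("short", "long"):
                node = f"{par}[{sid},{cell}]"
                if node in post.draws:
                    rows.append({"subject_id": sid, "condition": cond, "parameter": par,
                                 "cell": cell, "estimate": float(post.stacked(node).mean())})
    return pd.DataFrame(rows)
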
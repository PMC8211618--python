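"""Hierarchical Bayesian estimation of diffusion parameters for dual-task data.

Model structure (one independent model per task, both conditions jointly):

* drift rate ``v`` and non-decision time ``t0`` vary by condition
  (between-subjects: SF vs LF) x SOA class (within-subjects: short vs long;
  medium SOAs are excluded before fitting);
* boundary separation ``a`` is estimated per subject with one common
  population distribution (no condition effect);
* the start point is fixed at a/2, the diffusion constant at 1, and all
  inter-trial variability parameters at 0;
* subject-level parameters are draws from normal population laws whose means
  and spreads are the group-level nodes; the trial-level likelihood is the
  Wiener first-passage density of accuracy-coded response times.

Sampling is Metropolis-within-Gibbs: group means and variances have conjugate
Gibbs updates (normal and inverse-gamma); subject-level parameters use
scalar random-walk Metropolis steps whose proposal scales adapt during
burn-in.  At least two chains are run so that rank-normalized split R-hat is
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .wfpt import _loglik_lower_kernel

__all__ = ["ModelSpec", "PosteriorDraws", "ChainDiagnostics", "fit_hierarchical",
           "rhat", "prior_predictive_rt", "CELLS"]

CELLS = ("short", "long")

# weakly informative hyperpriors (seconds / evidence units)
_PRIORS = {
    "a": {"m0": 1.5, "s0": 1.0, "alpha0": 2.0, "beta0": 0.09},
    "v": {"m0": 2.0, "s0": 3.0, "alpha0": 2.0, "beta0": 0.25},
    "t0": {"m0": 0.4, "s0": 0.5, "alpha0": 2.0, "beta0": 0.01},
}

_RHAT_THRESHOLD = 1.05
_ADAPT_WINDOW = 25
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one per-task hierarchical fit.

    n_samples draws are taken per chain and the first burn_in discarded, so
    each chain retains ``n_samples - burn_in`` draws (5000 at the defaults).
    """

    task: int
    n_samples: int = 6000
    burn_in: int = 1000
    n_chains: int = 2
    seed: int = 0
    subject_sweeps: int = 2

    def __post_init__(self) -> None:
        if self.task not in (1, 2):
            raise ValueError("task must be 1 or 2")
        if not (0 < self.burn_in < self.n_samples):
            raise ValueError("burn_in must be positive and smaller than n_samples")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for convergence checks")
        if self.subject_sweeps < 1:
            raise ValueError("subject_sweeps must be at least 1")

    @property
    def n_retained(self) -> int:
        return self.n_samples - self.burn_in


@dataclass
class PosteriorDraws:
    """MCMC draws organized chain x iteration x node.

    ``draws`` maps node names to (n_chains, n_retained) arrays.  Group nodes
    are named ``mu_a``, ``sigma_a``, ``mu_v[SF,short]`` ...; subject nodes
    ``a[SF01]``, ``v[SF01,short]``, ``t0[SF01,short]`` ...  t0 nodes are in
    seconds, drifts in evidence/s.
    """

    draws: dict[str, np.ndarray]
    subjects: dict[str, str]  # subject_id -> condition
    spec: ModelSpec

    @property
    def nodes(self) -> list[str]:
        return list(self.draws)

    def stacked(self, node: str) -> np.ndarray:
        """All chains concatenated, one flat vector per node."""
        return self.draws[node].reshape(-1)

    def group_node(self, param: str, condition: str | None = None,
                   cell: str | None = None, kind: str = "mu") -> np.ndarray:
        name = f"{kind}_{param}" if condition is None else f"{kind}_{param}[{condition},{cell}]"
        return self.stacked(name)

    def to_dataframe(self) -> pd.DataFrame:
        n_chains, n_draws = next(iter(self.draws.values())).shape
        frames = []
        for node, arr in self.draws.items():
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "node": node,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class ChainDiagnostics:
    rhat: dict[str, float]
    acceptance: dict[str, float]
    converged: bool
    threshold: float = _RHAT_THRESHOLD
    notes: str = ""

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def summary(self) -> dict:
        return {
            "converged": self.converged,
            "max_rhat": self.max_rhat,
            "threshold": self.threshold,
            "mean_acceptance": float(np.mean(list(self.acceptance.values()))),
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Cell:
    rt_correct: np.ndarray  # seconds
    rt_error: np.ndarray
    min_rt: float

    @property
    def n(self) -> int:
        return len(self.rt_correct) + len(self.rt_error)


def _prepare(trials: pd.DataFrame, task: int) -> tuple[dict[str, dict[str, _Cell]], dict[str, str]]:
    """Split trials into per-subject short/long cells of one task.

    Expects exclusion rules already applied; drops no-go rows (for task 2)
    and medium-SOA trials here.  Returns ({sid: {cell: _Cell}}, {sid: cond}).
    """
    df = trials[~trials["is_nogo"].astype(bool)] if task == 2 else trials
    soas = np.sort(df["soa_ms"].unique())
    if len(soas) < 2:
        raise ValueError("need at least two SOA levels to define short and long cells")
    cell_of = {soas[0]: "short", soas[-1]: "long"}
    df = df[df["soa_ms"].isin([soas[0], soas[-1]])]
    rt_col, ok_col = f"rt{task}_ms", f"correct{task}"
    data: dict[str, dict[str, _Cell]] = {}
    conditions: dict[str, str] = {}
    for (sid, soa), g in df.groupby(["subject_id", "soa_ms"], sort=True):
        rts = g[rt_col].to_numpy(dtype=float) / 1000.0
        ok = g[ok_col].to_numpy(dtype=bool)
        cell = _Cell(rt_correct=rts[ok], rt_error=rts[~ok], min_rt=float(rts.min()))
        data.setdefault(str(sid), {})[cell_of[soa]] = cell
        conditions[str(sid)] = str(g["condition"].iloc[0])
    return data, conditions


def _cell_loglik(cell: _Cell, a: float, v: float, t0: float) -> float:
    """Accuracy-coded WFPT log-likelihood of one subject-cell.

    Correct responses absorb at the upper boundary, which by symmetry of the
    unbiased start equals the lower-boundary density under drift -v.
    """
    ll = 0.0
    if len(cell.rt_correct):
        ll = _loglik_lower_kernel(cell.rt_correct, a, -v, t0)
        if ll == -np.inf:
            return -np.inf
    if len(cell.rt_error):
        ll_e = _loglik_lower_kernel(cell.rt_error, a, v, t0)
        if ll_e == -np.inf:
            return -np.inf
        ll += ll_e
    return ll


# ---------------------------------------------------------------------------
# conjugate group updates


def _update_mu(values: np.ndarray, sigma: float, prior: dict, rng) -> float:
    tau0 = 1.0 / prior["s0"] ** 2
    taun = tau0 + len(values) / sigma**2
    mean = (prior["m0"] * tau0 + values.sum() / sigma**2) / taun
    return rng.normal(mean, np.sqrt(1.0 / taun))


def _update_sigma(values: np.ndarray, mu: float, prior: dict, rng) -> float:
    alpha = prior["alpha0"] + len(values) / 2.0
    beta = prior["beta0"] + float(((values - mu) ** 2).sum()) / 2.0
    return float(np.sqrt(beta / rng.gamma(alpha)))


# ---------------------------------------------------------------------------
# the sampler


def _init_state(data, conditions, rng):
    """Data-driven jittered initial values for one chain."""
    state = {"a": {}, "v": {}, "t0": {}}
    for sid, cells in data.items():
        state["a"][sid] = 1.5 * np.exp(rng.normal(0, 0.05))
        state["v"][sid] = {}
        state["t0"][sid] = {}
        for cell_name, cell in cells.items():
            n_c, n_e = len(cell.rt_correct), len(cell.rt_error)
            acc = (n_c + 0.5) / (cell.n + 1.0)
            v0 = np.clip(np.log(acc / (1 - acc)) / 1.5, 0.3, 5.0)
            state["v"][sid][cell_name] = v0 * np.exp(rng.normal(0, 0.1))
            state["t0"][sid][cell_name] = cell.min_rt * rng.uniform(0.4, 0.6)
    return state


def _group_cells(conditions) -> list[str]:
    return sorted(set(conditions.values()))


def _run_chain(data, conditions, spec: ModelSpec, chain_seed, progress=None):
    rng = np.random.default_rng(chain_seed)
    state = _init_state(data, conditions, rng)
    subjects = sorted(data)
    groups = _group_cells(conditions)
    # populated (condition, cell) combinations
    cells_by_cond = {
        c: sorted({cell for sid in subjects if conditions[sid] == c for cell in data[sid]},
                  key=CELLS.index)
        for c in groups
    }

    # group-level state
    g = {"mu_a": 1.5, "sigma_a": 0.3}
    for c in groups:
        for cell in cells_by_cond[c]:
            g[f"mu_v[{c},{cell}]"] = 2.0
            g[f"sigma_v[{c},{cell}]"] = 0.5
            g[f"mu_t0[{c},{cell}]"] = 0.3
            g[f"sigma_t0[{c},{cell}]"] = 0.1

    # cached per subject-cell log-likelihoods
    ll = {sid: {cell: _cell_loglik(data[sid][cell], state["a"][sid],
                                   state["v"][sid][cell], state["t0"][sid][cell])
                for cell in data[sid]} for sid in subjects}

    # proposal scales and acceptance bookkeeping per scalar node
    scales, acc_n, acc_k = {}, {}, {}
    for sid in subjects:
        scales[f"a[{sid}]"] = 0.08
        for cell in data[sid]:
            scales[f"v[{sid},{cell}]"] = 0.25
            scales[f"t0[{sid},{cell}]"] = 0.015
    for k in scales:
        acc_n[k] = 0
        acc_k[k] = 0

    node_names = list(g) + list(scales)
    retained = {k: np.empty(spec.n_retained) for k in node_names}

    def metro(key, current, logp_cur, logp_fn, lo=None):
        prop = current + rng.normal(0, scales[key])
        acc_n[key] += 1
        if lo is not None and prop <= lo:
            return current, logp_cur, False
        logp_prop = logp_fn(prop)
        if np.log(rng.random()) < logp_prop - logp_cur:
            acc_k[key] += 1
            return prop, logp_prop, True
        return current, logp_cur, False

    for it in range(spec.n_samples):
        adapting = it < spec.burn_in
        # several Metropolis sweeps over the subject level per kept draw:
        # a, v and t0 are posterior-correlated within a subject, and repeated
        # single-site sweeps cut the resulting autocorrelation
        for _sweep in range(spec.subject_sweeps):
            for sid in subjects:
                cond = conditions[sid]
                cells = data[sid]
                a_s = state["a"][sid]

                # boundary separation: touches every cell of the subject
                key = f"a[{sid}]"

                def logp_a(a_new, sid=sid, cells=cells):
                    lp = -0.5 * ((a_new - g["mu_a"]) / g["sigma_a"]) ** 2
                    for cell in cells:
                        lp_c = _cell_loglik(cells[cell], a_new, state["v"][sid][cell],
                                            state["t0"][sid][cell])
                        if lp_c == -np.inf:
                            return -np.inf
                        lp += lp_c
                    return lp

                cur_lp = -0.5 * ((a_s - g["mu_a"]) / g["sigma_a"]) ** 2 + sum(ll[sid].values())
                new_a, _, accepted = metro(key, a_s, cur_lp, logp_a, lo=0.0)
                if accepted:
                    state["a"][sid] = new_a
                    for cell in cells:
                        ll[sid][cell] = _cell_loglik(cells[cell], new_a, state["v"][sid][cell],
                                                     state["t0"][sid][cell])

                for cell in cells:
                    a_s = state["a"][sid]

                    key = f"v[{sid},{cell}]"
                    mu, sig = g[f"mu_v[{cond},{cell}]"], g[f"sigma_v[{cond},{cell}]"]
                    v_cur = state["v"][sid][cell]

                    def logp_v(v_new, sid=sid, cell=cell, a_s=a_s, mu=mu, sig=sig):
                        lp_c = _cell_loglik(data[sid][cell], a_s, v_new, state["t0"][sid][cell])
                        return -np.inf if lp_c == -np.inf else lp_c - 0.5 * ((v_new - mu) / sig) ** 2

                    cur_lp = ll[sid][cell] - 0.5 * ((v_cur - mu) / sig) ** 2
                    v_new, lp_new, accepted = metro(key, v_cur, cur_lp, logp_v)
                    if accepted:
                        state["v"][sid][cell] = v_new
                        ll[sid][cell] = lp_new + 0.5 * ((v_new - mu) / sig) ** 2

                    key = f"t0[{sid},{cell}]"
                    mu, sig = g[f"mu_t0[{cond},{cell}]"], g[f"sigma_t0[{cond},{cell}]"]
                    t_cur = state["t0"][sid][cell]

                    def logp_t(t_new, sid=sid, cell=cell, a_s=a_s, mu=mu, sig=sig):
                        lp_c = _cell_loglik(data[sid][cell], a_s, state["v"][sid][cell], t_new)
                        return -np.inf if lp_c == -np.inf else lp_c - 0.5 * ((t_new - mu) / sig) ** 2

                    cur_lp = ll[sid][cell] - 0.5 * ((t_cur - mu) / sig) ** 2
                    t_new, lp_new, accepted = metro(key, t_cur, cur_lp, logp_t, lo=0.0)
                    if accepted:
                        state["t0"][sid][cell] = t_new
                        ll[sid][cell] = lp_new + 0.5 * ((t_new - mu) / sig) ** 2

        # conjugate group updates
        a_vals = np.array([state["a"][sid] for sid in subjects])
        g["mu_a"] = _update_mu(a_vals, g["sigma_a"], _PRIORS["a"], rng)
        g["sigma_a"] = _update_sigma(a_vals, g["mu_a"], _PRIORS["a"], rng)
        for c in groups:
            members = [sid for sid in subjects if conditions[sid] == c]
            for cell in cells_by_cond[c]:
                have = [sid for sid in members if cell in data[sid]]
                for par in ("v", "t0"):
                    vals = np.array([state[par][sid][cell] for sid in have])
                    mu_key, sig_key = f"mu_{par}[{c},{cell}]", f"sigma_{par}[{c},{cell}]"
                    g[mu_key] = _update_mu(vals, g[sig_key], _PRIORS[par], rng)
                    g[sig_key] = _update_sigma(vals, g[mu_key], _PRIORS[par], rng)

        # proposal-scale adaptation, burn-in only
        if adapting and (it + 1) % _ADAPT_WINDOW == 0:
            for k in scales:
                if acc_n[k]:
                    rate = acc_k[k] / acc_n[k]
                    scales[k] *= float(np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5)))
                    acc_n[k] = 0
                    acc_k[k] = 0

        if it >= spec.burn_in:
            j = it - spec.burn_in
            for k in g:
                retained[k][j] = g[k]
            for sid in subjects:
                retained[f"a[{sid}]"][j] = state["a"][sid]
                for cell in data[sid]:
                    retained[f"v[{sid},{cell}]"][j] = state["v"][sid][cell]
                    retained[f"t0[{sid},{cell}]"][j] = state["t0"][sid][cell]

    rates = {k: (acc_k[k] / acc_n[k] if acc_n[k] else np.nan) for k in scales}
    return retained, rates


def fit_hierarchical(trials: pd.DataFrame, spec: ModelSpec) -> tuple[PosteriorDraws, ChainDiagnostics]:
    """Fit the per-task hierarchical diffusion model to a preprocessed trial table.

    ``trials`` should already have the exclusion cascade applied (keep the
    fitted task's error trials for accuracy coding); medium-SOA and no-go
    rows are removed here.  Fully seeded: identical spec + data -> identical
    draws.  Non-convergence is reported in the diagnostics, never raised.
    """
    data, conditions = _prepare(trials, spec.task)
    if not data:
        raise ValueError("no trials to fit")
    chain_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    per_chain, rates_all = [], []
    for cs in chain_seeds:
        retained, rates = _run_chain(data, conditions, spec, cs)
        per_chain.append(retained)
        rates_all.append(rates)

    draws = {k: np.stack([pc[k] for pc in per_chain]) for k in per_chain[0]}
    post = PosteriorDraws(draws=draws, subjects=conditions, spec=spec)
    rhats = {k: rhat(v) for k, v in draws.items()}
    acceptance = {k: float(np.mean([r[k] for r in rates_all])) for k in rates_all[0]}
    max_r = max(rhats.values())
    diag = ChainDiagnostics(
        rhat=rhats,
        acceptance=acceptance,
        converged=bool(max_r < _RHAT_THRESHOLD),
        notes="" if max_r < _RHAT_THRESHOLD else
        f"max R-hat {max_r:.3f} >= {_RHAT_THRESHOLD}; inspect traces / rerun longer",
    )
    return post, diag


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of one node, draws shaped (chains, draws)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("R-hat needs a (chains >= 2, draws) array")
    if np.ptp(draws) == 0:  # constant node: chains agree trivially
        return 1.0
    return float(az.rhat(draws, method="rank"))


def prior_predictive_rt(n: int, rng: np.random.Generator) -> np.ndarray:
    """Mean response times (s) implied by n prior draws of (a, v, t0).

    Used to sanity-check that the default priors put mass on plausible RTs.
    """
    out = np.empty(n)
    for i in range(n):
        a = abs(rng.normal(_PRIORS["a"]["m0"], 0.3)) + 1e-3
        v = rng.normal(_PRIORS["v"]["m0"], 0.5)
        t0 = abs(rng.normal(_PRIORS["t0"]["m0"], 0.1))
        if v == 0:
            mean_dt = a**2 / 4
        else:
            mean_dt = (a / (2 * v)) * np.tanh(a * v / 2)
        out[i] = t0 + mean_dt
    return out
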
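"""End-to-end orchestration: generate -> preprocess -> RT stats -> fit ->
posterior comparisons -> report.

A run is driven by a :class:`RunConfig` (experiment preset, generator mode
per condition, sampling profile, seed) and leaves a directory of delimited
text artifacts plus a JSON manifest with SHA-256 hashes of every file, so a
rerun with the same config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import preset, PRESET_NAMES
from .hier import ModelSpec, fit_hierarchical
from .io import write_trials, write_sidecar, write_draws, read_trials, read_sidecar, read_draws
from .posterior import bayesian_p, diff_of_diffs, participant_posterior_means
from .preprocess import exclude_trials, aggregate_cells
from .rt_stats import mixed_anova_2x3, welch_t, paired_t, bonferroni
from .simulate import default_population, simulate_experiment

log = logging.getLogger("prpddm")

__all__ = ["RunConfig", "run_pipeline", "make_report",
           "generate_stage", "preprocess_stage", "rtstats_stage", "fit_stage", "compare_stage"]

# (n_samples, burn_in, n_chains, n_subjects_per_condition)
_PROFILES = {
    "tiny": {"n_samples": 500, "burn_in": 150, "n_chains": 2, "n_subjects": 4, "n_blocks": 2},
    "scaled": {"n_samples": 2000, "burn_in": 500, "n_chains": 2, "n_subjects": 20, "n_blocks": 5},
    "full": {"n_samples": 6000, "burn_in": 1000, "n_chains": 2, "n_subjects": 20, "n_blocks": 5},
}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run.

    mode_sf / mode_lf select the generative process per condition ('serial'
    or 'parallel'); profile picks the sampling effort ('tiny' for smoke runs,
    'scaled' for recovery-sized runs, 'full' for the complete 6000/1000 draws).
    """

    experiment: str = "exp1"
    mode_sf: str = "parallel"
    mode_lf: str = "serial"
    profile: str = "tiny"
    outdir: str = "prpddm_run"
    seed: int = 0
    fit: bool = True
    tasks: tuple[int, ...] = (1, 2)
    plots: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in PRESET_NAMES:
            raise ValueError(f"experiment must be one of {PRESET_NAMES}")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {tuple(_PROFILES)}")
        for m in (self.mode_sf, self.mode_lf):
            if m not in ("serial", "parallel"):
                raise ValueError(f"modes must be 'serial' or 'parallel', got {m!r}")

    @property
    def profile_params(self) -> dict:
        return _PROFILES[self.profile]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig, outdir: Path):
        self.outdir = outdir
        self.data = {"version": __version__, "config": {**asdict(config)},
                     "stages": {}, "files": {}}
        self.data["config"]["tasks"] = list(config.tasks)

    def record(self, stage: str, files: list[Path], **params) -> None:
        self.data["stages"][stage] = {"params": params,
                                      "files": [f.name for f in files]}
        for f in files:
            self.data["files"][f.name] = _sha256(f)
        self.save()

    def save(self) -> None:
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True))


def generate_stage(config: RunConfig, outdir: Path, manifest: _Manifest) -> pd.DataFrame:
    prof = config.profile_params
    modes = {"SF": config.mode_sf, "LF": config.mode_lf}
    configs = {c: preset(config.experiment, c,
                         n_subjects_per_condition=prof["n_subjects"],
                         n_blocks=prof["n_blocks"], seed=config.seed)
               for c in ("SF", "LF")}
    populations = {c: default_population(modes[c]) for c in ("SF", "LF")}
    trials, sidecar = simulate_experiment(configs, populations, seed=config.seed)
    write_trials(trials, outdir / "trials.csv")
    write_sidecar(sidecar, outdir / "ground_truth.json")
    manifest.record("generate", [outdir / "trials.csv", outdir / "ground_truth.json"],
                    experiment=config.experiment, modes=modes, seed=config.seed)
    log.info("generated %d trials for %d subjects", len(trials),
             trials["subject_id"].nunique())
    return trials


def preprocess_stage(config: RunConfig, outdir: Path, manifest: _Manifest,
                     trials: pd.DataFrame) -> pd.DataFrame:
    drop_nogo = config.experiment == "exp3"
    retained, report = exclude_trials(trials, drop_nogo=drop_nogo)
    cells = aggregate_cells(retained, trials)
    write_trials(retained, outdir / "retained.csv")
    cells.to_csv(outdir / "cells.csv", index=False)
    (outdir / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    manifest.record("preprocess",
                    [outdir / "retained.csv", outdir / "cells.csv",
                     outdir / "exclusion_report.json"],
                    drop_nogo=drop_nogo, rt_window=[200, 2000])
    log.info("preprocess: removed %.2f%% of trials", 100 * report.fraction_removed)
    return cells


def rtstats_stage(config: RunConfig, outdir: Path, manifest: _Manifest,
                  cells: pd.DataFrame) -> pd.DataFrame:
    rows = []
    lines = []
    for task in (1, 2):
        for dv in ("mean_rt", "error_rate"):
            tab = mixed_anova_2x3(cells, dv=dv, task=task)
            t = tab.table.copy()
            t.insert(0, "task", task)
            t.insert(1, "dv", dv)
            rows.append(t)
            lines.append(tab.report())
    anova = pd.concat(rows, ignore_index=True)
    anova.to_csv(outdir / "anova.csv", index=False)
    (outdir / "anova_report.txt").write_text("\n\n".join(lines) + "\n")
    manifest.record("rtstats", [outdir / "anova.csv", outdir / "anova_report.txt"])
    return anova


def fit_stage(config: RunConfig, outdir: Path, manifest: _Manifest,
              trials: pd.DataFrame) -> dict:
    prof = config.profile_params
    posts = {}
    files = []
    for task in config.tasks:
        fit_trials, _ = exclude_trials(trials, drop_nogo=True, error_policy=f"task{task}")
        spec = ModelSpec(task=task, n_samples=prof["n_samples"], burn_in=prof["burn_in"],
                         n_chains=prof["n_chains"], seed=config.seed + task)
        post, diag = fit_hierarchical(fit_trials, spec)
        posts[task] = (post, diag)
        csv, man = outdir / f"draws_task{task}.csv", outdir / f"draws_task{task}.json"
        write_draws(post, csv, man)
        diag_file = outdir / f"diagnostics_task{task}.json"
        diag_file.write_text(json.dumps(diag.summary(), indent=2))
        files += [csv, man, diag_file]
        if not diag.converged:
            log.warning("task %d fit did not converge: %s", task, diag.notes)
    manifest.record("fit", files, profile=config.profile)
    return posts


def compare_stage(config: RunConfig, outdir: Path, manifest: _Manifest, posts: dict) -> pd.DataFrame:
    rows = []
    # within-model posterior-proportion comparisons, per task x parameter x condition
    for task, (post, diag) in posts.items():
        conditions = sorted(set(post.subjects.values()))
        for par in ("v", "t0"):
            for cond in conditions:
                try:
                    short = post.group_node(par, cond, "short")
                    long_ = post.group_node(par, cond, "long")
                except KeyError:
                    continue
                direction = "less" if par == "v" else "greater"
                res = bayesian_p(short, long_, direction=direction,
                                 provenance=f"task{task} {par}[{cond}] short vs long")
                rows.append({"task": task, "parameter": par, "condition": cond,
                             "kind": res.kind, "comparison": "short vs long",
                             "direction": res.direction, "P": res.P,
                             "substantial": res.substantial, "converged": diag.converged})
        if {"SF", "LF"} <= set(conditions):
            try:
                res = diff_of_diffs(
                    post.group_node("t0", "SF", "short"), post.group_node("t0", "SF", "long"),
                    post.group_node("t0", "LF", "short"), post.group_node("t0", "LF", "long"),
                    direction="less",
                    provenance=f"task{task} t0 SOA effect, SF vs LF")
                rows.append({"task": task, "parameter": "t0", "condition": "SF-LF",
                             "kind": res.kind, "comparison": "diff of diffs",
                             "direction": res.direction, "P": res.P,
                             "substantial": res.substantial, "converged": diag.converged})
            except KeyError:
                pass

    # across-model t tests on participant posterior means
    if set(posts) == {1, 2}:
        means = {t: participant_posterior_means(posts[t][0]) for t in (1, 2)}
        for par in ("v", "t0"):  # Bonferroni family: one per parameter
            tests, labels = [], []
            m1 = means[1][(means[1]["parameter"] == par) & (means[1]["cell"] == "short")]
            m2 = means[2][(means[2]["parameter"] == par) & (means[2]["cell"] == "short")]
            merged = m1.merge(m2, on=["subject_id", "condition"], suffixes=("_t1", "_t2"))
            for cond, g in merged.groupby("condition"):
                if len(g) >= 2:
                    tests.append(paired_t(g["estimate_t2"] - g["estimate_t1"]))
                    labels.append((cond, "task2 vs task1, short"))
            for res, (cond, lab) in zip(bonferroni(tests), labels):
                rows.append({"task": 0, "parameter": par, "condition": cond,
                             "kind": res.flavor, "comparison": lab, "direction": "two-sided",
                             "P": np.nan, "substantial": bool(res.p_adjusted < 0.05),
                             "statistic": res.statistic, "df": res.df,
                             "p_raw": res.p_raw, "p_bonf": res.p_adjusted,
                             "converged": True})
    comp = pd.DataFrame(rows)
    comp.to_csv(outdir / "comparisons.csv", index=False)
    manifest.record("compare", [outdir / "comparisons.csv"])
    return comp


def make_report(outdir: Path, plots: bool = False) -> str:
    """Assemble a plain-text report from the artifacts present in ``outdir``.

    Missing stages are marked as such rather than failing.  With
    ``plots=True`` writes mean-RT-by-SOA line plots and posterior violin
    plots alongside.
    """
    outdir = Path(outdir)
    sections = []

    cells_f = outdir / "cells.csv"
    if cells_f.exists():
        cells = pd.read_csv(cells_f)
        tab = (cells.groupby(["task", "condition", "soa_ms"])["mean_rt"]
               .mean().unstack("soa_ms").round(1))
        sections.append("Mean RT (ms) by task, condition and SOA:\n" + tab.to_string())
        if plots:
            _plot_rt(cells, outdir / "mean_rt.png")
    else:
        sections.append("[cell means missing]")

    anova_f = outdir / "anova_report.txt"
    sections.append(anova_f.read_text().strip() if anova_f.exists() else "[ANOVA missing]")

    for task in (1, 2):
        diag_f = outdir / f"diagnostics_task{task}.json"
        if diag_f.exists():
            diag = json.loads(diag_f.read_text())
            status = "converged" if diag["converged"] else "NOT CONVERGED"
            sections.append(f"Task {task} fit: {status} (max R-hat {diag['max_rhat']:.3f})")
            if plots:
                try:
                    post = read_draws(outdir / f"draws_task{task}.csv",
                                      outdir / f"draws_task{task}.json")
                    _plot_violins(post, task, outdir / f"posterior_task{task}.png")
                except FileNotFoundError:
                    pass
        else:
            sections.append(f"[task {task} fit missing]")

    comp_f = outdir / "comparisons.csv"
    if comp_f.exists():
        comp = pd.read_csv(comp_f)
        bayes = comp[comp["kind"] == "bayesian_P"]
        lines = [f"  task {r.task} {r.parameter}[{r.condition}] {r.comparison} "
                 f"({r.direction}): P = {r.P:.3f}"
                 f"{' *' if r.substantial else ''}" for r in bayes.itertuples()]
        sections.append("Posterior comparisons (P > 0.950 marked *):\n" + "\n".join(lines))
    else:
        sections.append("[posterior comparisons missing]")

    text = "\n\n".join(sections) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def _plot_rt(cells: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, task in zip(axes, (1, 2)):
        sub = cells[cells["task"] == task]
        for cond, g in sub.groupby("condition"):
            m = g.groupby("soa_ms")["mean_rt"].mean()
            ax.plot(m.index, m.values, marker="o", label=cond)
        ax.set_title(f"Task {task}")
        ax.set_xlabel("SOA (ms)")
    axes[0].set_ylabel("mean RT (ms)")
    axes[0].legend(title="condition")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_violins(post, task: int, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted(set(post.subjects.values()))
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, par in zip(axes, ("v", "t0")):
        data, labels = [], []
        for cond in conditions:
            for cell in ("short", "long"):
                node = f"mu_{par}[{cond},{cell}]"
                if node in post.draws:
                    data.append(post.stacked(node))
                    labels.append(f"{cond}\n{cell}")
        if data:
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(labels) + 1), labels)
        ax.set_title(f"Task {task}: group {par}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with a stage-named error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    stage = "generate"
    try:
        trials = generate_stage(config, outdir, manifest)
        stage = "preprocess"
        cells = preprocess_stage(config, outdir, manifest, trials)
        stage = "rtstats"
        rtstats_stage(config, outdir, manifest, cells)
        if config.fit:
            stage = "fit"
            posts = fit_stage(config, outdir, manifest, trials)
            stage = "compare"
            compare_stage(config, outdir, manifest, posts)
        stage = "report"
        make_report(outdir, plots=config.plots)
        manifest.record("report", [outdir / "report.txt"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir
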
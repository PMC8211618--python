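"""Plain-text persistence: trial tables, sidecars, posterior draws, configs.

Trial tables are comma-separated with the fixed header
``subject_id,condition,block,trial,soa_ms,is_nogo,correct1,correct2,rt1_ms,rt2_ms``;
a no-go trial's rt2 is an empty field.  Posterior draws are stored as a long
CSV (chain, draw, node, value) next to a JSON manifest recording the model
spec, subjects and node list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hier import ModelSpec, PosteriorDraws
from .simulate import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "write_sidecar", "read_sidecar",
           "write_draws", "read_draws", "load_config"]


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("is_nogo", "correct1", "correct2"):
        df[col] = df[col].astype(bool)
    return df[TRIAL_COLUMNS]


def write_sidecar(sidecar: dict, path) -> None:
    Path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_draws(post: PosteriorDraws, csv_path, manifest_path) -> None:
    post.to_dataframe().to_csv(csv_path, index=False, float_format="%.10g")
    manifest = {
        "spec": {"task": post.spec.task, "n_samples": post.spec.n_samples,
                 "burn_in": post.spec.burn_in, "n_chains": post.spec.n_chains,
                 "seed": post.spec.seed},
        "subjects": post.subjects,
        "nodes": post.nodes,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_draws(csv_path, manifest_path) -> PosteriorDraws:
    manifest = json.loads(Path(manifest_path).read_text())
    df = pd.read_csv(csv_path)
    spec = ModelSpec(**manifest["spec"])
    draws = {}
    for node, g in df.groupby("node", sort=False):
        g = g.sort_values(["chain", "draw"])
        n_chains = g["chain"].nunique()
        draws[node] = g["value"].to_numpy().reshape(n_chains, -1)
    missing = set(manifest["nodes"]) - set(draws)
    if missing:
        raise ValueError(f"draw file lacks nodes listed in manifest: {sorted(missing)[:5]}")
    return PosteriorDraws(draws=draws, subjects=manifest["subjects"], spec=spec)


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
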
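"""Generative models of dual-task (PRP) behaviour.

Two explicit mechanisms produce trial-level data from stage parameters
(stimulus encoding, a diffusion decision stage, motor execution per task):

* **serial** (response-selection bottleneck): the Task-2 decision stage may
  start only once the Task-1 decision has finished, so at short SOAs the
  waiting time ("slack") is appended to Task-2's response time.
* **parallel** (capacity sharing): both decision stages run concurrently and,
  while they overlap, a limited central capacity is split — Task 1
  accumulates at ``share_1 * v_1`` and Task 2 at ``(1 - share_1) * v_2``.

Response time per task = encoding + decision duration + motor duration, with
RT2 measured from Task-2 stimulus onset.  Correctness is upper-boundary
absorption of the trial's diffusion walk (accuracy coding).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from . import _walkers
from .design import DesignConfig, build_schedule

__all__ = [
    "GenerativeParams",
    "PopulationSds",
    "default_population",
    "simulate_fpt",
    "simulate_fpt_batch",
    "serial_compose",
    "simulate_trial_serial",
    "simulate_trial_parallel",
    "sample_subject_params",
    "simulate_subject",
    "simulate_experiment",
    "TRIAL_COLUMNS",
]

DT_DEFAULT = 1e-4  # Euler step, seconds (0.1 ms)
CAP_DEFAULT = 10.0  # hard absorption cap, seconds

TRIAL_COLUMNS = [
    "subject_id", "condition", "block", "trial", "soa_ms",
    "is_nogo", "correct1", "correct2", "rt1_ms", "rt2_ms",
]

# population truncation bounds for subject-level parameter draws
_BOUNDS = {
    "encode": (1.0, np.inf),   # ms
    "motor": (1.0, np.inf),    # ms
    "a": (0.2, np.inf),        # evidence units
    "v": (0.2, np.inf),        # evidence / s; drift points toward correct
    "share": (0.05, 0.95),
}


@dataclass(frozen=True)
class GenerativeParams:
    """Per-subject true stage parameters of the dual-task generator.

    Durations are in ms, boundaries in evidence units, drifts in evidence/s.
    ``share_1`` is the Task-1 capacity share during decision overlap and is
    only meaningful in parallel mode.
    """

    encode_1: float
    motor_1: float
    a_1: float
    v_1: float
    encode_2: float
    motor_2: float
    a_2: float
    v_2: float
    mode: str = "serial"
    share_1: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("serial", "parallel"):
            raise ValueError(f"mode must be 'serial' or 'parallel', got {self.mode!r}")
        for name in ("encode_1", "motor_1", "encode_2", "motor_2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a_1 <= 0 or self.a_2 <= 0:
            raise ValueError("boundary separations must be positive")
        if not (0.0 < self.share_1 < 1.0):
            raise ValueError(f"share_1 must lie in (0, 1), got {self.share_1}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PopulationSds:
    """Between-subject standard deviations (same units as the means)."""

    encode: float = 20.0
    motor: float = 15.0
    a: float = 0.15
    v: float = 0.25
    share: float = 0.05

    def __post_init__(self) -> None:
        for name in ("encode", "motor", "a", "v", "share"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} sd must be non-negative")


def default_population(mode: str, *, v_1: float = 3.2, v_2: float = 2.2) -> tuple[GenerativeParams, PopulationSds]:
    """Default group-level means and spreads of the study conditions.

    The means give single-task RTs around 500 ms (Task 1) / 570 ms (Task 2)
    with error rates of roughly 1% and 4% — the regime of simple two-choice
    colour/identity discriminations.
    """
    means = GenerativeParams(
        encode_1=150.0, motor_1=100.0, a_1=1.5, v_1=v_1,
        encode_2=150.0, motor_2=100.0, a_2=1.5, v_2=v_2,
        mode=mode, share_1=0.7,
    )
    return means, PopulationSds()


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_fpt_batch(a: float, v: float, n: int, rng: np.random.Generator,
                       dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT):
    """n Euler-Maruyama first-passage draws from z = a/2 with s = 1.

    Returns (decision_times_ms, hit_upper, flagged); flagged walks were not
    absorbed within ``cap`` seconds.
    """
    if a <= 0:
        raise ValueError("boundary separation must be positive")
    if dt <= 0:
        raise ValueError("step size must be positive")
    times, upper, flagged = _walkers.fpt_batch(a, v, n, dt, cap, _child_seed(rng))
    return times * 1000.0, upper, flagged


def simulate_fpt(a: float, v: float, rng: np.random.Generator,
                 dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT) -> tuple[float, bool]:
    """One first-passage draw: (decision time in ms, hit_upper).

    Raises if the walk is not absorbed within ``cap`` seconds (never silently
    truncates).
    """
    times, upper, flagged = simulate_fpt_batch(a, v, 1, rng, dt=dt, cap=cap)
    if flagged[0]:
        raise RuntimeError(f"diffusion walk not absorbed within {cap} s (a={a}, v={v})")
    return float(times[0]), bool(upper[0])


def serial_compose(params: GenerativeParams, soa_ms: float, d1_ms: float, d2_ms: float) -> tuple[float, float]:
    """Deterministic serial-mode RT assembly given decision durations (ms).

    rt1 = encode_1 + d1 + motor_1 on the Task-1 clock; the Task-2 decision
    starts at max(soa + encode_2, encode_1 + d1); rt2 is measured from Task-2
    stimulus onset.  Exposed as the test hook for the bottleneck composition.
    """
    rt1 = params.encode_1 + d1_ms + params.motor_1
    start2 = max(soa_ms + params.encode_2, params.encode_1 + d1_ms)
    rt2 = (start2 - soa_ms) + d2_ms + params.motor_2
    return rt1, rt2


def _check_soas(soa_ms) -> np.ndarray:
    soas = np.atleast_1d(np.asarray(soa_ms, dtype=float))
    if np.any(soas < 0):
        raise ValueError("negative SOAs are not part of the design")
    return soas


def _run_walk(params: GenerativeParams, soas_ms: np.ndarray, rng: np.random.Generator,
              dt: float, cap: float):
    soas_s = soas_ms / 1000.0
    args = (
        soas_s,
        params.encode_1 / 1000.0, params.motor_1 / 1000.0, params.a_1, params.v_1,
        params.encode_2 / 1000.0, params.motor_2 / 1000.0, params.a_2, params.v_2,
    )
    if params.mode == "serial":
        rt1, rt2, c1, c2, flagged = _walkers.serial_walk(*args, dt, cap, _child_seed(rng))
    else:
        rt1, rt2, c1, c2, flagged = _walkers.parallel_walk(
            *args, params.share_1, dt, cap, _child_seed(rng))
    return rt1 * 1000.0, rt2 * 1000.0, c1, c2, flagged


def _simulate_trials(params: GenerativeParams, soa_ms, rng: np.random.Generator,
                     dt: float, cap: float):
    soas = _check_soas(soa_ms)
    rt1, rt2, c1, c2, flagged = _run_walk(params, soas, rng, dt, cap)
    if np.any(flagged):
        raise RuntimeError(
            f"{int(flagged.sum())} diffusion walk(s) not absorbed within {cap} s; "
            "check drift and boundary values")
    return rt1, rt2, c1, c2


def simulate_trial_serial(params: GenerativeParams, soa_ms: float, rng: np.random.Generator,
                          dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT) -> dict:
    """One serial-bottleneck trial -> rt1_ms, rt2_ms, correct1, correct2."""
    if params.mode != "serial":
        raise ValueError("params.mode must be 'serial'")
    rt1, rt2, c1, c2 = _simulate_trials(params, soa_ms, rng, dt, cap)
    return {"rt1_ms": float(rt1[0]), "rt2_ms": float(rt2[0]),
            "correct1": bool(c1[0]), "correct2": bool(c2[0])}


def simulate_trial_parallel(params: GenerativeParams, soa_ms: float, rng: np.random.Generator,
                            dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT) -> dict:
    """One capacity-sharing trial -> rt1_ms, rt2_ms, correct1, correct2."""
    if params.mode != "parallel":
        raise ValueError("params.mode must be 'parallel'")
    rt1, rt2, c1, c2 = _simulate_trials(params, soa_ms, rng, dt, cap)
    return {"rt1_ms": float(rt1[0]), "rt2_ms": float(rt2[0]),
            "correct1": bool(c1[0]), "correct2": bool(c2[0])}


def sample_subject_params(means: GenerativeParams, sds: PopulationSds,
                          rng: np.random.Generator) -> GenerativeParams:
    """Draw one subject's parameters from truncated-normal population laws.

    Truncation bounds keep durations and boundaries positive (module-level
    constants); a mean outside its bound is rejected outright.
    """
    def draw(mean: float, sd: float, kind: str) -> float:
        lo, hi = _BOUNDS[kind]
        if not (lo <= mean <= hi):
            raise ValueError(f"population mean {mean} outside truncation bounds {lo, hi} for {kind}")
        if sd == 0:
            return mean
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return x
        raise RuntimeError(f"truncated draw failed for {kind}: mean {mean}, sd {sd}")

    return replace(
        means,
        encode_1=draw(means.encode_1, sds.encode, "encode"),
        motor_1=draw(means.motor_1, sds.motor, "motor"),
        a_1=draw(means.a_1, sds.a, "a"),
        v_1=draw(means.v_1, sds.v, "v"),
        encode_2=draw(means.encode_2, sds.encode, "encode"),
        motor_2=draw(means.motor_2, sds.motor, "motor"),
        a_2=draw(means.a_2, sds.a, "a"),
        v_2=draw(means.v_2, sds.v, "v"),
        share_1=draw(means.share_1, sds.share, "share"),
    )


def simulate_subject(subject_id: str, condition: str, params: GenerativeParams,
                     config: DesignConfig, rng: np.random.Generator,
                     dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT) -> pd.DataFrame:
    """One subject's full test phase as a trial table.

    No-go trials are generated with identical Task-1 processing; their Task-2
    response time is undefined (NaN) and correct2 is recorded True (no
    response was required).
    """
    soas, nogo = build_schedule(config, rng)
    rt1, rt2, c1, c2 = _simulate_trials(params, soas, rng, dt, cap)
    n = config.n_trials
    df = pd.DataFrame({
        "subject_id": subject_id,
        "condition": condition,
        "block": np.repeat(np.arange(1, config.n_blocks + 1), config.trials_per_block),
        "trial": np.arange(1, n + 1),
        "soa_ms": soas,
        "is_nogo": nogo,
        "correct1": c1,
        "correct2": np.where(nogo, True, c2),
        "rt1_ms": rt1,
        "rt2_ms": np.where(nogo, np.nan, rt2),
    })
    return df[TRIAL_COLUMNS]


def simulate_experiment(configs: dict[str, DesignConfig],
                        populations: dict[str, tuple[GenerativeParams, PopulationSds]],
                        seed: int,
                        dt: float = DT_DEFAULT, cap: float = CAP_DEFAULT,
                        iri_floor: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Full between-subjects dataset plus a ground-truth parameter sidecar.

    configs and populations are keyed by condition label ('SF', 'LF'); each
    condition's subjects are drawn from its own population (mode included).
    Distinct subjects receive independent RNG substreams, so the dataset is
    reproducible from ``seed`` alone.  ``iri_floor`` (ms), if set, post-hoc
    raises rt2 so that no go trial has an inter-response interval below the
    floor — a stress-test option, off by default.
    """
    if set(configs) != set(populations):
        raise ValueError("configs and populations must have identical condition keys")
    frames = []
    sidecar: dict[str, dict] = {}
    ss = np.random.SeedSequence(seed)
    conditions = sorted(configs)
    children = iter(ss.spawn(sum(configs[c].n_subjects_per_condition for c in conditions)))
    for cond in conditions:
        config = configs[cond]
        means, sds = populations[cond]
        for i in range(config.n_subjects_per_condition):
            sid = f"{cond}{i + 1:02d}"
            rng = np.random.default_rng(next(children))
            params = sample_subject_params(means, sds, rng)
            frames.append(simulate_subject(sid, cond, params, config, rng, dt, cap))
            sidecar[sid] = {"condition": cond, **params.to_dict()}
    trials = pd.concat(frames, ignore_index=True)
    if iri_floor is not None:
        go = ~trials["is_nogo"]
        min_rt2 = trials["rt1_ms"] - trials["soa_ms"] + iri_floor
        trials.loc[go, "rt2_ms"] = np.maximum(trials.loc[go, "rt2_ms"], min_rt2[go])
    return trials, sidecar
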
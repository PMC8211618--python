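"""Experimental designs for dual-task (PRP) studies.

A design is a between-subjects SOA-frequency manipulation: the SF group sees
80% short / 10% medium / 10% long stimulus-onset asynchronies, the LF group
the mirror image.  The test phase is 5 blocks x 80 trials with exact per-block
SOA counts; a no-go variant withholds the Task-2 response on a fixed fraction
of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["DesignConfig", "preset", "build_schedule", "PRESET_NAMES"]


@dataclass(frozen=True)
class DesignConfig:
    """One between-subjects condition's trial-schedule geometry.

    soa_levels : three SOAs in ms, strictly increasing (short, medium, long)
    soa_weights : per-level probabilities; exact per-block counts are enforced
    frequent_level : index into soa_levels that carries the 80% weight
        (0 identifies the SF condition, 2 the LF condition)
    nogo_rate : fraction of trials with no Task-2 response required
    """

    soa_levels: tuple[float, float, float]
    soa_weights: tuple[float, float, float]
    frequent_level: int
    n_blocks: int = 5
    trials_per_block: int = 80
    nogo_rate: float = 0.0
    n_subjects_per_condition: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.soa_levels) != 3 or len(self.soa_weights) != 3:
            raise ValueError("exactly three SOA levels and weights are required")
        if not all(x < y for x, y in zip(self.soa_levels, self.soa_levels[1:])):
            raise ValueError(f"SOA levels must be strictly increasing: {self.soa_levels}")
        if abs(sum(self.soa_weights) - 1.0) > 1e-9:
            raise ValueError(f"SOA weights must sum to 1: {self.soa_weights}")
        if any(w < 0 for w in self.soa_weights):
            raise ValueError("SOA weights must be non-negative")
        if self.frequent_level not in (0, 1, 2):
            raise ValueError("frequent_level must index one of the three SOA levels")
        if max(self.soa_weights) != self.soa_weights[self.frequent_level]:
            raise ValueError("frequent_level must carry the largest weight")
        if not (0 <= self.nogo_rate < 1):
            raise ValueError(f"nogo_rate must lie in [0, 1): {self.nogo_rate}")
        for name in ("n_blocks", "trials_per_block", "n_subjects_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for w in self.soa_weights:
            c = w * self.trials_per_block
            if abs(c - round(c)) > 1e-9:
                raise ValueError(
                    f"weight {w} x {self.trials_per_block} trials/block is not a whole "
                    "number of trials; exact per-block SOA counts are required"
                )
        c = self.nogo_rate * self.trials_per_block
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"nogo_rate {self.nogo_rate} x {self.trials_per_block} trials/block is "
                "not a whole number of no-go trials per block"
            )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def block_counts(self) -> tuple[int, int, int]:
        """Exact number of trials per SOA level within each block."""
        return tuple(int(round(w * self.trials_per_block)) for w in self.soa_weights)

    @property
    def condition(self) -> str:
        return "SF" if self.frequent_level == 0 else "LF"

    def to_dict(self) -> dict:
        return asdict(self)


_SOA_SETS = {"exp1": (100.0, 300.0, 800.0), "exp2": (300.0, 500.0, 1000.0), "exp3": (100.0, 300.0, 800.0)}
_NOGO = {"exp1": 0.0, "exp2": 0.0, "exp3": 0.175}

PRESET_NAMES = tuple(sorted(_SOA_SETS))


def preset(experiment: str, condition: str, *, n_subjects_per_condition: int = 20,
           n_blocks: int = 5, trials_per_block: int = 80, seed: int = 0) -> DesignConfig:
    """Canonical design for one experiment x condition.

    experiment : 'exp1' (SOAs 100/300/800 ms), 'exp2' (300/500/1000 ms) or
    'exp3' (as exp1 plus 17.5% Task-2 no-go trials); condition : 'SF' or 'LF'.
    """
    if experiment not in _SOA_SETS:
        raise ValueError(f"unknown experiment preset {experiment!r}; choose from {PRESET_NAMES}")
    if condition not in ("SF", "LF"):
        raise ValueError(f"condition must be 'SF' or 'LF', got {condition!r}")
    frequent = 0 if condition == "SF" else 2
    weights = [0.1, 0.1, 0.1]
    weights[frequent] = 0.8
    return DesignConfig(
        soa_levels=_SOA_SETS[experiment],
        soa_weights=tuple(weights),
        frequent_level=frequent,
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        nogo_rate=_NOGO[experiment],
        n_subjects_per_condition=n_subjects_per_condition,
        seed=seed,
    )


def build_schedule(config: DesignConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Randomized trial order for one subject with exact per-block composition.

    Returns (soa_ms, is_nogo) arrays of length ``config.n_trials``.  Every
    block holds exactly ``block_counts`` trials of each SOA level and exactly
    ``nogo_rate * trials_per_block`` no-go trials, shuffled independently of
    SOA within the block.
    """
    counts = config.block_counts
    n_nogo = int(round(config.nogo_rate * config.trials_per_block))
    soas, nogos = [], []
    for _ in range(config.n_blocks):
        block = np.repeat(np.asarray(config.soa_levels, dtype=float), counts)
        rng.shuffle(block)
        flags = np.zeros(config.trials_per_block, dtype=bool)
        flags[rng.choice(config.trials_per_block, size=n_nogo, replace=False)] = True
        soas.append(block)
        nogos.append(flags)
    return np.concatenate(soas), np.concatenate(nogos)
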
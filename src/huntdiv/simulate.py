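"""Synthetic group hunts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: predators arrive in staggered subgroups, the next attacker is drawn
among present individuals with probability proportional to a per-individual
motivation weight (excluding the immediately preceding attacker, which
enforces the no-adjacent-repeat property any observed sequence log has),
dash-sequence lengths are geometric with a termination probability that may
step up across strata of the hunt, dashes are spaced by exponential
intervals, and each dash captures prey independently.

Defaults mirror the scale of a real recorded hunt: 34 individuals arriving
in three waves over a ~2800 s recording, ~700 dashes in ~300 sequences,
mean sequence length ~2.4 and an overall capture rate of ~0.155 per dash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import Hunt
from .subgroups import GroupAssignment, appearance_order

__all__ = ["HuntConfig", "GroundTruth", "generate_hunt", "null_hunt", "true_group_assignment"]


@dataclass(frozen=True)
class HuntConfig:
    """Parameters of the generative hunt model.

    ``termination_p`` may be a single probability or one per equal-duration
    stratum of the hunt (an increasing sequence plants a time trend).
    ``attack_weights`` and ``capture_p`` may be scalars applied to all
    individuals or per-individual sequences (concatenated over groups in
    arrival order).
    """

    group_sizes: tuple[int, ...] = (14, 11, 9)
    arrival_times_s: tuple[float, ...] = (0.0, 900.0, 1800.0)
    attack_weights: float | tuple[float, ...] = 1.0
    termination_p: float | tuple[float, ...] = (0.33, 0.40, 0.46, 0.52)
    capture_p: float | tuple[float, ...] = 0.155
    mean_interdash_s: float = 3.9
    duration_s: float = 2789.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.arrival_times_s):
            raise ValueError("one arrival time per group required")
        if any(g < 2 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if any(b <= a for a, b in zip(self.arrival_times_s, self.arrival_times_s[1:])):
            raise ValueError("arrival times must be strictly increasing")
        for p in np.atleast_1d(self.termination_p):
            if not 0 < p <= 1:
                raise ValueError("termination probabilities must be in (0, 1]")
        for c in np.atleast_1d(self.capture_p):
            if not 0 <= c <= 1:
                raise ValueError("capture probabilities must be in [0, 1]")
        for w in np.atleast_1d(self.attack_weights):
            if w <= 0:
                raise ValueError("attack weights must be positive")
        if self.mean_interdash_s <= 0 or self.duration_s <= 0:
            raise ValueError("mean_interdash_s and duration_s must be positive")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.group_sizes))

    def individual_ids(self) -> list[str]:
        width = len(str(self.n_individuals))
        return [f"m{i+1:0{width}d}" for i in range(self.n_individuals)]

    def per_individual(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(self.n_individuals, arr[0])
        if arr.size != self.n_individuals:
            raise ValueError("per-individual parameter has wrong length")
        return arr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HuntConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("group_sizes", "arrival_times_s", "attack_weights", "termination_p", "capture_p"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    groups: tuple[tuple[str, ...], ...]
    arrival_times_s: tuple[float, ...]
    attack_weights: dict
    termination_p: tuple[float, ...]
    capture_p: dict
    forced_repeat: bool  # True if the previous-attacker exclusion ever had to be relaxed

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": [list(g) for g in self.groups],
                "arrival_times_s": list(self.arrival_times_s),
                "attack_weights": self.attack_weights,
                "termination_p": list(self.termination_p),
                "capture_p": self.capture_p,
                "forced_repeat": self.forced_repeat,
            },
            indent=2,
        )


def generate_hunt(config: HuntConfig) -> tuple[Hunt, GroundTruth]:
    """Simulate one hunt; deterministic given config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    ids = config.individual_ids()
    weights = config.per_individual(config.attack_weights)
    capture_p = config.per_individual(config.capture_p)
    term_p = np.atleast_1d(np.asarray(config.termination_p, dtype=float))
    n_strata = term_p.size

    group_of = np.repeat(np.arange(len(config.group_sizes)), config.group_sizes)
    arrivals = np.asarray(config.arrival_times_s, dtype=float)

    times: list[float] = []
    attackers: list[int] = []
    captures: list[bool] = []
    prev = -1
    forced_repeat = False
    t = 0.0
    while True:
        t_next = t + rng.exponential(config.mean_interdash_s)
        present = np.flatnonzero(arrivals[group_of] <= t_next)
        if present.size == 0:
            t = float(arrivals.min())
            continue
        if t_next > config.duration_s:
            break
        candidates = present[present != prev]
        if candidates.size == 0:
            candidates = present  # lone present individual: allow repeat
            forced_repeat = True
        w = weights[candidates]
        attacker = int(rng.choice(candidates, p=w / w.sum()))
        stratum = min(n_strata - 1, int(n_strata * t_next / config.duration_s))
        length = int(rng.geometric(term_p[stratum]))
        t = t_next
        emitted = 0
        while emitted < length:
            times.append(t)
            attackers.append(attacker)
            captures.append(bool(rng.random() < capture_p[attacker]))
            emitted += 1
            if emitted < length:
                t_dash = t + rng.exponential(config.mean_interdash_s)
                if t_dash > config.duration_s:
                    break
                t = t_dash
        prev = attacker

    if not times:
        raise ValueError("configuration produced an empty hunt; increase duration")

    hunt = Hunt(
        time_s=np.array(times),
        individual_id=np.array([ids[a] for a in attackers], dtype=object),
        capture=np.array(captures, dtype=bool),
        duration_s=config.duration_s,
        metadata={"generator": "huntdiv.simulate", "seed": config.seed},
    )
    bounds = np.concatenate([[0], np.cumsum(config.group_sizes)]).astype(int)
    truth = GroundTruth(
        groups=tuple(tuple(ids[a:b]) for a, b in zip(bounds[:-1], bounds[1:])),
        arrival_times_s=tuple(float(a) for a in arrivals),
        attack_weights={ids[i]: float(weights[i]) for i in range(len(ids))},
        termination_p=tuple(float(p) for p in term_p),
        capture_p={ids[i]: float(capture_p[i]) for i in range(len(ids))},
        forced_repeat=forced_repeat,
    )
    return hunt, truth


def null_hunt(seed: int | None = None, **overrides) -> tuple[Hunt, GroundTruth]:
    """A hunt with all heterogeneity switched off: equal attack weights,
    constant termination probability, one shared capture probability.

    Used for calibration studies; any :class:`HuntConfig` field can still be
    overridden, but weights and probabilities stay scalar.
    """
    cfg = HuntConfig(
        attack_weights=1.0,
        termination_p=0.42,
        capture_p=0.155,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    for name in ("attack_weights", "termination_p", "capture_p"):
        if np.atleast_1d(getattr(cfg, name)).size != 1:
            raise ValueError(f"null_hunt requires a scalar {name}")
    return generate_hunt(cfg)


def true_group_assignment(hunt: Hunt, truth: GroundTruth, threshold: float = float("nan")) -> GroupAssignment:
    """Ground-truth subgroup assignment in the analysis' coordinates.

    Epoch starts are the dash-sequence indices of each true group's first
    attack; groups that never attacked are dropped.  Useful for running the
    pipeline's null models with planted (rather than inferred) groups.
    """
    first_seq: dict[str, int] = {
        rec.individual_id: rec.first_sequence_index for rec in appearance_order(hunt)
    }
    groups, starts = [], []
    for members in truth.groups:
        seen = [m for m in members if m in first_seq]
        if seen:
            groups.append(tuple(members))
            starts.append(min(first_seq[m] for m in seen))
    order = np.argsort(starts, kind="stable")
    return GroupAssignment(
        threshold=threshold,
        groups=tuple(groups[i] for i in order),
        epoch_starts=tuple(int(starts[i]) for i in order),
    )
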
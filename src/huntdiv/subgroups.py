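"""Arrival-subgroup segmentation from the order of first appearances.

In open-membership marine hunts, predators join the hunt in waves rather
than all at once.  The segmentation works entirely on the ordered list of
dash sequences: for each pair of consecutively appearing individuals
(m_i, m_{i+1}) it counts the number of dash sequences d_i performed by
already-present individuals strictly between the two first appearances, and
normalizes by the number i of individuals already present.  If every present
individual were equally likely to attack next, a newcomer would wait on
average i sequences, so r_i = d_i / i near or below 1 marks individuals
arriving together, while a large r_i marks a lull before a new wave.

m_{i+1} founds a new subgroup when r_i >= h (a long lull ended) and
r_{i+1} <= min(1, r_i) (the next appearance followed promptly).  The
minimum subgroup size is 2, so the last appearer never founds a group on
its own.  The threshold h is a tuning knob with no single correct value;
analyses carry a grid of h values forward rather than selecting one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .events import DashSequence, Hunt, derive_dash_sequences

__all__ = [
    "AppearanceRecord",
    "GapStatistic",
    "GroupAssignment",
    "appearance_order",
    "gap_statistics",
    "segment_groups",
    "group_count_profile",
]


@dataclass(frozen=True)
class AppearanceRecord:
    individual_id: str
    rank: int  # 1-based order of first dash sequence
    first_sequence_index: int  # 0-based index into the dash-sequence list


@dataclass(frozen=True)
class GapStatistic:
    """Normalized appearance gap for the pair (m_i, m_{i+1})."""

    i: int  # rank of the earlier individual
    d: int  # dash sequences strictly between the two first appearances
    r: float  # d / i


@dataclass(frozen=True)
class GroupAssignment:
    threshold: float
    groups: tuple[tuple[str, ...], ...]  # ordered by founding rank
    epoch_starts: tuple[int, ...]  # dash-sequence index of each group's first attack

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, individual_id: str) -> int:
        """0-based subgroup index of an individual."""
        for g, members in enumerate(self.groups):
            if individual_id in members:
                return g
        raise KeyError(individual_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "groups": [list(g) for g in self.groups],
                "epoch_starts": list(self.epoch_starts),
            },
            indent=2,
        )


def _sequences(hunt: Hunt) -> list[DashSequence]:
    return derive_dash_sequences(hunt)


def appearance_order(hunt: Hunt) -> list[AppearanceRecord]:
    """One record per distinct individual, ranked by its first dash sequence."""
    records: list[AppearanceRecord] = []
    seen: set[str] = set()
    for idx, seq in enumerate(_sequences(hunt)):
        if seq.individual_id not in seen:
            seen.add(seq.individual_id)
            records.append(
                AppearanceRecord(
                    individual_id=seq.individual_id,
                    rank=len(records) + 1,
                    first_sequence_index=idx,
                )
            )
    return records


def gap_statistics(hunt: Hunt) -> list[GapStatistic]:
    """d_i and r_i = d_i / i for each consecutive appearance pair.

    d_i counts dash sequences strictly between the first sequence of m_i and
    the first sequence of m_{i+1}; both boundary sequences are excluded.
    """
    order = appearance_order(hunt)
    if len(order) < 2:
        raise ValueError("gap statistics need at least 2 individuals")
    gaps = []
    for a, b in zip(order[:-1], order[1:]):
        d = b.first_sequence_index - a.first_sequence_index - 1
        gaps.append(GapStatistic(i=a.rank, d=d, r=d / a.rank))
    return gaps


def segment_groups(
    gaps: Sequence[GapStatistic],
    h: float,
    order: Sequence[AppearanceRecord] | None = None,
) -> GroupAssignment:
    """Scan the appearance order and cut it into subgroups at threshold h.

    m_1 founds group 1.  m_{i+1} founds a new group iff r_i >= h and
    r_{i+1} <= min(1, r_i).  The minimum subgroup size is 2: the last
    appearer never founds, and a founding that would leave the current
    group with a single member is suppressed.  When ``order`` is omitted,
    placeholder IDs ``m1..mM`` and epoch starts in appearance-rank
    coordinates are used.
    """
    if h <= 0:
        raise ValueError("threshold h must be positive")
    r = [g.r for g in gaps]
    m = len(r) + 1  # number of individuals
    if order is not None and len(order) != m:
        raise ValueError("appearance order inconsistent with gap list")

    founders = [0]  # 0-based appearance index of each group's first member
    for i in range(1, m - 1):  # candidate founder m_{i+1}, 1-based i in 1..M-2
        if r[i - 1] >= h and r[i] <= min(1.0, r[i - 1]) and i - founders[-1] >= 2:
            founders.append(i)

    ids = [rec.individual_id for rec in order] if order is not None else [f"m{k+1}" for k in range(m)]
    first_idx = (
        [rec.first_sequence_index for rec in order] if order is not None else list(range(m))
    )
    bounds = founders + [m]
    groups = tuple(tuple(ids[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
    epoch_starts = tuple(first_idx[f] for f in founders)
    return GroupAssignment(threshold=float(h), groups=groups, epoch_starts=epoch_starts)


def segment_hunt(hunt: Hunt, h: float) -> GroupAssignment:
    """Convenience: appearance order + gap statistics + segmentation."""
    order = appearance_order(hunt)
    if len(order) < 2:
        return GroupAssignment(
            threshold=float(h),
            groups=(tuple(rec.individual_id for rec in order),),
            epoch_starts=(0,),
        )
    return segment_groups(gap_statistics(hunt), h, order=order)


def group_count_profile(hunt: Hunt, h_grid: Sequence[float]) -> dict[float, int]:
    """Number of subgroups at each threshold; non-increasing in h."""
    if len(h_grid) == 0:
        raise ValueError("h_grid must be non-empty")
    if any(b <= a for a, b in zip(h_grid, list(h_grid)[1:])):
        raise ValueError("h_grid must be strictly ascending")
    return {float(h): segment_hunt(hunt, h).n_groups for h in h_grid}
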
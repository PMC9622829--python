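"""Equal-access null model of prey access for individuals present at the school.

The null hypothesis is that every predator present at the prey school has the
same chance of performing the next dash.  Individuals are deemed present from
the moment the first member of their arrival subgroup attacks, and are assumed
to stay until the end of the hunt.  The number of opportunities equals the
number of observed dashes, so expected dash counts conserve the observed
total by construction: during an epoch with n present individuals and D
dashes, each present individual expects D/n dashes.

Percentile bands come from a Monte-Carlo simulation in which every dash is
reassigned uniformly at random among the individuals present at that moment —
equivalently, per-epoch counts are multinomial with equal cell probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Hunt, derive_dash_sequences
from .resampling import nearest_rank
from .subgroups import GroupAssignment

__all__ = [
    "PresenceSchedule",
    "AccessExpectation",
    "GroupAccessResult",
    "presence_schedule",
    "expected_dashes",
    "simulate_access_null",
    "newly_arrived_vs_present",
]


@dataclass(frozen=True)
class PresenceSchedule:
    """Per-individual presence interval in dash-index coordinates.

    ``arrival_index[i]`` is the event index of the first dash of the first
    attacking member of i's subgroup; presence runs to the end of the hunt.
    ``epoch_bounds`` are half-open event-index windows [start, end) between
    consecutive subgroup arrivals, aligned with the subgroup order.
    """

    arrival_index: dict[str, int]
    epoch_bounds: tuple[tuple[int, int], ...]
    n_events: int

    def present_in_epoch(self, epoch: int) -> list[str]:
        start = self.epoch_bounds[epoch][0]
        return [i for i, a in self.arrival_index.items() if a <= start]


@dataclass(frozen=True)
class AccessExpectation:
    individual_id: str
    epoch: int
    observed_dashes: int
    expected_dashes: float
    null_mean: float | None = None
    lo_2_5: float | None = None
    hi_97_5: float | None = None
    replicates: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class GroupAccessResult:
    """Observed vs expected mean dashes per member of a newly arrived subgroup,
    restricted to the epoch between its arrival and the next subgroup's."""

    group_index: int
    n_members: int
    n_present: int
    n_dashes_epoch: int
    observed_mean: float
    expected_mean: float
    lo_2_5: float
    hi_97_5: float
    replicates: int
    seed: int | None


def presence_schedule(hunt: Hunt, groups: GroupAssignment) -> PresenceSchedule:
    seqs = derive_dash_sequences(hunt)
    assigned = {i for g in groups.groups for i in g}
    missing = set(hunt.individuals) - assigned
    if missing:
        raise ValueError(f"individuals missing from group assignment: {sorted(missing)}")

    arrival_events = [seqs[s].start_index for s in groups.epoch_starts]
    arrival_index = {
        ind: arrival_events[g] for g, members in enumerate(groups.groups) for ind in members
    }
    bounds = tuple(
        (arrival_events[k], arrival_events[k + 1] if k + 1 < len(arrival_events) else hunt.n_events)
        for k in range(len(arrival_events))
    )
    return PresenceSchedule(
        arrival_index=arrival_index, epoch_bounds=bounds, n_events=hunt.n_events
    )


def _epoch_tables(hunt: Hunt, schedule: PresenceSchedule):
    """Per epoch: (present ids, dash count, observed per-individual counts)."""
    out = []
    for k, (start, end) in enumerate(schedule.epoch_bounds):
        present = sorted(schedule.present_in_epoch(k), key=lambda i: schedule.arrival_index[i])
        ids_in_epoch = hunt.individual_id[start:end]
        observed = {i: int(np.sum(ids_in_epoch == i)) for i in present}
        out.append((present, end - start, observed))
    return out


def expected_dashes(hunt: Hunt, schedule: PresenceSchedule) -> list[AccessExpectation]:
    """Closed-form equal-chance expectations: D_epoch / n_present per individual.

    Summed over individuals and epochs this reproduces the observed number of
    dashes exactly.
    """
    results = []
    for epoch, (present, n_dashes, observed) in enumerate(_epoch_tables(hunt, schedule)):
        exp = n_dashes / len(present)
        for ind in present:
            results.append(
                AccessExpectation(
                    individual_id=ind,
                    epoch=epoch,
                    observed_dashes=observed[ind],
                    expected_dashes=exp,
                )
            )
    return results


def simulate_access_null(
    hunt: Hunt,
    schedule: PresenceSchedule,
    replicates: int = 10**6,
    seed: int | None = None,
) -> list[AccessExpectation]:
    """Monte-Carlo percentile bands for per-individual, per-epoch dash counts.

    Each replicate assigns every dash uniformly at random to an individual
    present at that dash; within an epoch this is a symmetric multinomial
    over the present individuals, which is how it is sampled.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for epoch, (present, n_dashes, observed) in enumerate(_epoch_tables(hunt, schedule)):
        n = len(present)
        counts = rng.multinomial(n_dashes, np.full(n, 1.0 / n), size=replicates)
        exp = n_dashes / n
        for j, ind in enumerate(present):
            results.append(
                AccessExpectation(
                    individual_id=ind,
                    epoch=epoch,
                    observed_dashes=observed[ind],
                    expected_dashes=exp,
                    null_mean=float(counts[:, j].mean()),
                    lo_2_5=nearest_rank(counts[:, j], 2.5),
                    hi_97_5=nearest_rank(counts[:, j], 97.5),
                    replicates=replicates,
                    seed=seed,
                )
            )
    return results


def newly_arrived_vs_present(
    hunt: Hunt,
    groups: GroupAssignment,
    schedule: PresenceSchedule | None = None,
    replicates: int = 10**6,
    seed: int | None = None,
) -> list[GroupAccessResult]:
    """Observed vs expected mean dashes per member of each newly arrived subgroup.

    Subgroup k is scored only on the epoch from its own arrival until the next
    subgroup's arrival.  The first epoch's group matches its expectation by
    necessity (its members are the only ones present).  The null group total
    is Binomial(D_epoch, n_members/n_present) — the exact marginal of the
    equal-chance multinomial — and the band is on the per-member mean.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if schedule is None:
        schedule = presence_schedule(hunt, groups)
    rng = np.random.default_rng(seed)
    tables = _epoch_tables(hunt, schedule)
    out = []
    for k, (present, n_dashes, observed) in enumerate(tables):
        members = groups.groups[k]
        n_members = len(members)
        obs_mean = sum(observed.get(i, 0) for i in members) / n_members
        exp_mean = n_dashes / len(present)
        totals = rng.binomial(n_dashes, n_members / len(present), size=replicates)
        means = totals / n_members
        out.append(
            GroupAccessResult(
                group_index=k,
                n_members=n_members,
                n_present=len(present),
                n_dashes_epoch=n_dashes,
                observed_mean=float(obs_mean),
                expected_mean=float(exp_mean),
                lo_2_5=nearest_rank(means, 2.5),
                hi_97_5=nearest_rank(means, 97.5),
                replicates=replicates,
                seed=seed,
            )
        )
    return out
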
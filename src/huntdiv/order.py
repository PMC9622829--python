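"""Attack-order statistics: ABA turn interruptions and return-gap histograms.

The object of study is the ordered list of identities of the dash sequences
— who attacked, in turn order.  An *ABA pattern* is a triple of consecutive
sequences where the same individual A returns immediately after a single
interruption by any other individual B; an excess of ABA patterns over a
permutation null indicates motivated immediate returns rather than random
turn order.  The *return gap* generalizes this: for each pair of consecutive
sequences by the same individual, the number of intervening sequences by
others (an ABA pattern is a gap of 1).

The null preserves arrival structure: identities are shuffled uniformly
within each arrival epoch (the block of sequence slots between consecutive
subgroup arrivals), so each individual keeps its number of sequences per
epoch and never appears before its subgroup arrived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Hunt, derive_dash_sequences
from .resampling import ResamplingResult, nearest_rank, upper_tail_result
from .subgroups import GroupAssignment

__all__ = [
    "identity_order",
    "count_aba",
    "gap_histogram",
    "GapHistogram",
    "permute_within_epochs",
    "aba_permutation_test",
    "gap_null_bands",
]


def identity_order(hunt: Hunt) -> list[str]:
    """Identity of each dash sequence, in order; no two adjacent entries equal."""
    return [s.individual_id for s in derive_dash_sequences(hunt)]


def count_aba(order) -> int:
    """Number of (possibly overlapping) triples order[j] == order[j+2] != order[j+1]."""
    a = np.asarray(order, dtype=object)
    if len(a) < 3:
        return 0
    return int(np.sum((a[:-2] == a[2:]) & (a[:-2] != a[1:-1])))


def _gap_counts(codes: np.ndarray, cap: int) -> np.ndarray:
    """Histogram of return gaps; index g holds gap g, index cap pools >= cap.

    For each individual, each consecutive pair of its sequence slots
    contributes the number of intervening slots.  Index 0 (zero intervening
    sequences, i.e. adjacent equal labels) is impossible in observed orders
    but can occur in permuted ones; keeping the bin conserves the total
    count sum(n_i - 1) across replicates.
    """
    pos = np.argsort(codes, kind="stable")
    sorted_codes = codes[pos]
    same = sorted_codes[1:] == sorted_codes[:-1]
    gaps = (pos[1:] - pos[:-1])[same] - 1
    gaps = np.minimum(gaps, cap)
    return np.bincount(gaps, minlength=cap + 1).astype(float)


@dataclass(frozen=True)
class GapHistogram:
    """Observed return-gap counts, with optional null mean and percentile bands.

    Entry j is gap size j (intervening sequences); the final entry (index
    ``cap``) pools all gaps >= cap.  Index 0 is the merged-sequence artifact
    bin, always 0 for observed orders.
    """

    cap: int
    observed: tuple[float, ...]
    expected: tuple[float, ...] | None = None
    lo_2_5: tuple[float, ...] | None = None
    hi_97_5: tuple[float, ...] | None = None
    replicates: int | None = None
    seed: int | None = None


def gap_histogram(order, cap: int = 40) -> GapHistogram:
    order = list(order)
    codes, _ = _encode(order)
    return GapHistogram(cap=cap, observed=tuple(_gap_counts(codes, cap)))


def _encode(order) -> tuple[np.ndarray, list[str]]:
    uniq = sorted(set(order))
    lookup = {v: i for i, v in enumerate(uniq)}
    return np.array([lookup[v] for v in order], dtype=int), uniq


def _epoch_blocks(n_slots: int, groups: GroupAssignment) -> list[np.ndarray]:
    starts = list(groups.epoch_starts) + [n_slots]
    if starts[0] != 0:
        raise ValueError("first epoch must start at sequence slot 0")
    return [np.arange(a, b) for a, b in zip(starts[:-1], starts[1:]) if b > a]


def permute_within_epochs(order, groups: GroupAssignment, seed: int | None = None) -> list[str]:
    """Shuffle the identity labels uniformly within each arrival epoch.

    Per-individual sequence counts per epoch are preserved.  The permuted
    order may contain adjacent equal labels; it is returned slot-for-slot,
    not re-merged.
    """
    order = list(order)
    rng = np.random.default_rng(seed)
    out = list(order)
    for block in _epoch_blocks(len(order), groups):
        labels = [order[i] for i in block]
        perm = rng.permutation(len(block))
        for dst, src in zip(block, perm):
            out[dst] = labels[src]
    return out


def _permuted_codes(
    codes: np.ndarray, groups: GroupAssignment, rng: np.random.Generator, size: int
) -> np.ndarray:
    """(size, n) identity codes shuffled within epochs, vectorized over replicates."""
    n = len(codes)
    out = np.empty((size, n), dtype=codes.dtype)
    for block in _epoch_blocks(n, groups):
        keys = rng.random((size, len(block)))
        out[:, block] = codes[block][np.argsort(keys, axis=1)]
    return out


def aba_permutation_test(
    order,
    groups: GroupAssignment,
    replicates: int = 10**4,
    seed: int | None = None,
) -> ResamplingResult:
    """Upper-tail permutation test for an excess of ABA patterns."""
    order = list(order)
    codes, _ = _encode(order)
    observed = count_aba(order)
    rng = np.random.default_rng(seed)
    perm = _permuted_codes(codes, groups, rng, replicates)
    null = np.sum((perm[:, :-2] == perm[:, 2:]) & (perm[:, :-2] != perm[:, 1:-1]), axis=1)
    return upper_tail_result(observed, null, seed)


def gap_null_bands(
    order,
    groups: GroupAssignment,
    cap: int = 40,
    replicates: int = 10**4,
    seed: int | None = None,
) -> GapHistogram:
    """Return-gap histogram with per-bin null mean and 2.5/97.5 percentile bands."""
    order = list(order)
    codes, _ = _encode(order)
    observed = _gap_counts(codes, cap)
    rng = np.random.default_rng(seed)
    perm = _permuted_codes(codes, groups, rng, replicates)
    null = np.empty((replicates, cap + 1))
    for r in range(replicates):
        null[r] = _gap_counts(perm[r], cap)
    return GapHistogram(
        cap=cap,
        observed=tuple(observed),
        expected=tuple(null.mean(axis=0)),
        lo_2_5=tuple(nearest_rank(null[:, j], 2.5) for j in range(cap + 1)),
        hi_97_5=tuple(nearest_rank(null[:, j], 97.5) for j in range(cap + 1)),
        replicates=replicates,
        seed=seed,
    )
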
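"""Dash-sequence length modelling and inter-individual difference tests.

Sequence lengths are modelled as Geometric on {1, 2, ...}: a sequence ends
after each dash with probability p, so length L has P(L = k) = p(1-p)^(k-1)
and the maximum-likelihood estimate is p̂ = 1/mean(L).  Because every
sequence ends with exactly one terminating dash, the per-stratum proportion
of terminating dashes (sequences/dashes) estimates p, and a chi-squared test
for trend in proportions across consecutive strata of the hunt detects a
drift in p over time.

Inter-individual differences in mean sequence length are tested with a
stratified permutation test: sequence lengths are shuffled among sequence
slots within each stratum (so each individual keeps its number of sequences
and the time profile of lengths is preserved), and the test statistic is the
variance of per-individual mean lengths over individuals with at least
``min_sequences`` sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import Hunt, derive_dash_sequences
from .resampling import nearest_rank

__all__ = [
    "GeometricFit",
    "TrendTestResult",
    "VariancePermTest",
    "fit_geometric",
    "assign_strata",
    "termination_trend_test",
    "stratified_variance_permutation_test",
]


@dataclass(frozen=True)
class GeometricFit:
    p_hat: float
    n_sequences: int
    log_likelihood: float


def fit_geometric(lengths) -> GeometricFit:
    """MLE of the termination probability for lengths supported on {1, 2, ...}."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no lengths to fit")
    if np.any(lengths < 1):
        raise ValueError("lengths must be >= 1")
    n = lengths.size
    total = lengths.sum()
    p = n / total
    # loglik = n log p + (sum(L) - n) log(1 - p); second term vanishes if p = 1
    ll = n * math.log(p) + ((total - n) * math.log(1 - p) if p < 1 else 0.0)
    return GeometricFit(p_hat=float(p), n_sequences=int(n), log_likelihood=float(ll))


def assign_strata(hunt: Hunt, k: int, unit: str = "sequences") -> np.ndarray:
    """Assign each dash sequence (in order) to one of k consecutive strata.

    ``unit="sequences"`` (default) makes blocks of near-equal sequence counts
    (sizes differ by at most 1).  ``unit="dashes"`` cuts at near-equal
    cumulative dash counts; a sequence belongs to the stratum its first dash
    falls in.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = derive_dash_sequences(hunt)
    n = len(seqs)
    if unit == "sequences":
        out = np.empty(n, dtype=int)
        for s, block in enumerate(np.array_split(np.arange(n), k)):
            out[block] = s
        return out
    if unit == "dashes":
        total = hunt.n_events
        bounds = [total * j / k for j in range(1, k)]
        starts = np.array([s.start_index for s in seqs], dtype=float)
        return np.searchsorted(bounds, starts, side="right").astype(int)
    raise ValueError(f"unknown unit {unit!r}")


@dataclass(frozen=True)
class TrendTestResult:
    chi2: float
    df: int
    p_value: float
    successes: tuple[int, ...]  # terminating dashes (= sequences) per stratum
    trials: tuple[int, ...]  # dashes per stratum


def termination_trend_test(hunt: Hunt, k: int, unit: str = "sequences") -> TrendTestResult:
    """Cochran–Armitage chi-squared test for trend in the termination proportion.

    Stratum j contributes x_j terminating dashes (one per sequence) out of
    n_j dashes; scores are 1..k.  The statistic is the standard trend
    chi-square with 1 degree of freedom.
    """
    if k < 2:
        raise ValueError("trend test needs k >= 2 strata")
    seqs = derive_dash_sequences(hunt)
    strata = assign_strata(hunt, k, unit=unit)
    x = np.zeros(k, dtype=float)  # successes: sequences per stratum
    n = np.zeros(k, dtype=float)  # trials: dashes per stratum
    for s, seq in zip(strata, seqs):
        x[s] += 1
        n[s] += seq.length
    if np.any(n == 0):
        raise ValueError("stratum with zero dashes")
    scores = np.arange(1, k + 1, dtype=float)
    big_n = n.sum()
    pbar = x.sum() / big_n
    num = (x @ scores - pbar * (n @ scores)) ** 2
    den = pbar * (1 - pbar) * (n @ scores**2 - (n @ scores) ** 2 / big_n)
    # den = 0 when every dash terminates (or none do): no variation, no trend
    chi2 = float(num / den) if den > 0 else 0.0
    return TrendTestResult(
        chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        successes=tuple(int(v) for v in x),
        trials=tuple(int(v) for v in n),
    )


@dataclass(frozen=True)
class VariancePermTest:
    observed_variance: float
    null_mean: float
    lo_2_5: float
    hi_97_5: float
    p_value: float
    replicates: int
    seed: int | None
    min_sequences: int
    n_individuals_used: int
    individual_means: dict


def _permute_lengths_within_strata(
    lengths: np.ndarray, strata: np.ndarray, rng: np.random.Generator, size: int
) -> np.ndarray:
    """(size, n) matrix of lengths permuted independently within each stratum."""
    n = len(lengths)
    out = np.empty((size, n), dtype=lengths.dtype)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        block = lengths[idx]
        keys = rng.random((size, len(idx)))
        out[:, idx] = block[np.argsort(keys, axis=1)]
    return out


def stratified_variance_permutation_test(
    hunt: Hunt,
    k: int = 4,
    min_sequences: int = 5,
    replicates: int = 10**4,
    seed: int | None = None,
    unit: str = "sequences",
) -> VariancePermTest:
    """Permutation test for inter-individual differences in mean sequence length.

    Null: lengths are exchangeable among sequence slots within a stratum.
    Statistic: sample variance (n−1 denominator) of per-individual mean
    lengths, over individuals with at least ``min_sequences`` sequences.
    p = Pr(null >= observed) with the (b+1)/(m+1) correction.
    """
    seqs = derive_dash_sequences(hunt)
    lengths = np.array([s.length for s in seqs], dtype=float)
    ids = [s.individual_id for s in seqs]
    uniq = sorted(set(ids))
    owner = np.array([uniq.index(i) for i in ids], dtype=int)
    counts = np.bincount(owner, minlength=len(uniq)).astype(float)
    qual = np.flatnonzero(counts >= min_sequences)
    if len(qual) < 2:
        raise ValueError(
            f"need >= 2 individuals with >= {min_sequences} sequences, found {len(qual)}"
        )
    strata = assign_strata(hunt, k, unit=unit)

    onehot = np.zeros((len(lengths), len(uniq)))
    onehot[np.arange(len(lengths)), owner] = 1.0

    means = (lengths @ onehot) / counts
    observed = float(np.var(means[qual], ddof=1))

    rng = np.random.default_rng(seed)
    perm = _permute_lengths_within_strata(lengths, strata, rng, replicates)
    perm_means = (perm @ onehot[:, qual]) / counts[qual]
    null = np.var(perm_means, axis=1, ddof=1)

    b = int(np.sum(null >= observed))
    return VariancePermTest(
        observed_variance=observed,
        null_mean=float(null.mean()),
        lo_2_5=nearest_rank(null, 2.5),
        hi_97_5=nearest_rank(null, 97.5),
        p_value=(b + 1) / (replicates + 1),
        replicates=replicates,
        seed=seed,
        min_sequences=min_sequences,
        n_individuals_used=len(qual),
        individual_means={uniq[j]: float(means[j]) for j in qual},
    )
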
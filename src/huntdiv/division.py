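"""How the prey resource is divided among the predators.

Summaries and tests at the individual and subgroup level: cumulative-share
(Lorenz-style) curves of captures against attack-frequency rank, chi-squared
uniformity tests of dash-sequence counts within subgroups, Spearman rank
correlation of attack frequency and captures, a Monte-Carlo Fisher exact
test on the captures/dashes table (capture efficiencies), and the
captures-per-minute time series with a linear trend F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .events import Hunt, derive_dash_sequences
from .subgroups import GroupAssignment

__all__ = [
    "IndividualTally",
    "ShareCurve",
    "tally",
    "share_curve",
    "top_share",
    "uniformity_test",
    "rank_correlation",
    "capture_efficiency_test",
    "capture_rate_series",
]


@dataclass(frozen=True)
class IndividualTally:
    individual_id: str
    subgroup: int
    n_sequences: int
    n_dashes: int
    n_captures: int

    @property
    def capture_efficiency(self) -> float:
        return self.n_captures / self.n_dashes if self.n_dashes else 0.0


def tally(hunt: Hunt, groups: GroupAssignment) -> list[IndividualTally]:
    """Per-individual totals over the whole hunt, in descending-attack order."""
    seqs = derive_dash_sequences(hunt)
    agg: dict[str, list[int]] = {}
    for s in seqs:
        row = agg.setdefault(s.individual_id, [0, 0, 0])
        row[0] += 1
        row[1] += s.length
        row[2] += s.captures
    out = [
        IndividualTally(
            individual_id=i,
            subgroup=groups.group_of(i),
            n_sequences=row[0],
            n_dashes=row[1],
            n_captures=row[2],
        )
        for i, row in agg.items()
    ]
    return sorted(out, key=_attack_sort_key)


def _attack_sort_key(t: IndividualTally):
    # descending sequences, ties by descending captures then ID (deterministic)
    return (-t.n_sequences, -t.n_captures, t.individual_id)


@dataclass(frozen=True)
class ShareCurve:
    """Cumulative capture share against cumulative share of group members,
    members sorted in descending order of dash-sequence count.  Starts at
    (0, 0) and ends at (100, 100)."""

    pct_individuals: tuple[float, ...]
    pct_captures: tuple[float, ...]


def share_curve(tallies, within_subgroup: int | None = None) -> ShareCurve:
    rows = _select(tallies, within_subgroup)
    captures = np.array([t.n_captures for t in rows], dtype=float)
    total = captures.sum()
    if total == 0:
        raise ValueError("zero captures: share curve undefined")
    n = len(rows)
    return ShareCurve(
        pct_individuals=tuple(100.0 * k / n for k in range(n + 1)),
        pct_captures=tuple(100.0 * v / total for v in np.concatenate([[0.0], np.cumsum(captures)])),
    )


def top_share(tallies, fraction: float = 0.5, within_subgroup: int | None = None) -> float:
    """Percentage of captures taken by the ceil(fraction*N) most frequent attackers."""
    rows = _select(tallies, within_subgroup)
    captures = np.array([t.n_captures for t in rows], dtype=float)
    total = captures.sum()
    if total == 0:
        raise ValueError("zero captures: share undefined")
    k = math.ceil(fraction * len(rows))
    return float(100.0 * captures[:k].sum() / total)


def _select(tallies, within_subgroup: int | None) -> list[IndividualTally]:
    rows = [t for t in tallies if within_subgroup is None or t.subgroup == within_subgroup]
    if not rows:
        raise ValueError("no individuals selected")
    return sorted(rows, key=_attack_sort_key)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # any expected cell count < 5 (standard caveat)


def uniformity_test(counts) -> ChiSquareResult:
    """Pearson chi-squared test of equal dash-sequence counts across individuals."""
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("uniformity test needs >= 2 individuals")
    if counts.sum() == 0:
        raise ValueError("zero total count")
    chi2, p = stats.chisquare(counts)
    return ChiSquareResult(
        chi2=float(chi2),
        df=len(counts) - 1,
        p_value=float(p),
        low_expected=bool(counts.mean() < 5),
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    defined: bool


def rank_correlation(n_sequences, n_captures) -> SpearmanResult:
    """Spearman correlation (tie-corrected), two-sided p."""
    x = np.asarray(n_sequences, dtype=float)
    y = np.asarray(n_captures, dtype=float)
    if len(x) < 3:
        raise ValueError("rank correlation needs >= 3 individuals")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), defined=False)
    res = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(res.statistic), p_value=float(res.pvalue), defined=True)


@dataclass(frozen=True)
class MonteCarloFisherResult:
    p_value: float
    replicates: int
    seed: int | None
    degenerate: bool


def _log_table_prob(captures: np.ndarray, dashes: np.ndarray) -> np.ndarray:
    """Log probability of 2xN tables (captures vs misses per column) with fixed
    margins, i.e. the multivariate hypergeometric mass of the capture row."""
    total_c = captures.sum(axis=-1)
    total_n = dashes.sum()
    log_binom = (
        gammaln(dashes + 1)
        - gammaln(captures + 1)
        - gammaln(dashes - captures + 1)
    ).sum(axis=-1)
    return log_binom - (gammaln(total_n + 1) - gammaln(total_c + 1) - gammaln(total_n - total_c + 1))


def capture_efficiency_test(
    tallies, replicates: int = 10_000, seed: int | None = None
) -> MonteCarloFisherResult:
    """Monte-Carlo Fisher exact test for heterogeneous capture efficiencies.

    The 2xN table holds each individual's captures and non-capture dashes.
    Conditional on the margins, the capture row is multivariate
    hypergeometric; the p-value is the add-one-corrected proportion of
    sampled tables whose probability does not exceed the observed table's
    (with a small relative tolerance for floating-point ties).
    """
    rows = [t for t in tallies if t.n_dashes > 0]
    if len(rows) < 2:
        raise ValueError("efficiency test needs >= 2 individuals with >= 1 dash")
    dashes = np.array([t.n_dashes for t in rows], dtype=np.int64)
    captures = np.array([t.n_captures for t in rows], dtype=np.int64)
    total_c = int(captures.sum())
    if total_c == 0 or total_c == int(dashes.sum()):
        return MonteCarloFisherResult(p_value=1.0, replicates=0, seed=seed, degenerate=True)

    rng = np.random.default_rng(seed)
    obs_logp = float(_log_table_prob(captures, dashes))
    sim = rng.multivariate_hypergeometric(dashes, total_c, size=replicates)
    sim_logp = _log_table_prob(sim, dashes)
    b = int(np.sum(sim_logp <= obs_logp + 1e-7))
    return MonteCarloFisherResult(
        p_value=(b + 1) / (replicates + 1), replicates=replicates, seed=seed, degenerate=False
    )


@dataclass(frozen=True)
class CaptureRateResult:
    bin_s: float
    counts: tuple[int, ...]
    mean_per_bin: float
    se_per_bin: float
    min_count: int
    max_count: int
    slope: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    last_bin_coverage: float  # fraction of the last bin covered by the recording


def capture_rate_series(hunt: Hunt, bin_s: float = 60.0) -> CaptureRateResult:
    """Per-bin capture counts and an OLS linear trend F test on bin index.

    All bins enter the regression with raw counts; the trailing bin's
    coverage fraction is reported so per-minute rates can be rescaled in
    summaries.
    """
    duration = hunt.duration_s
    n_bins = int(math.ceil(duration / bin_s))
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    edges = np.arange(n_bins + 1) * bin_s
    edges[-1] = max(edges[-1], duration)
    counts, _ = np.histogram(hunt.time_s[hunt.capture], bins=edges)
    idx = np.arange(n_bins, dtype=float)
    res = stats.linregress(idx, counts.astype(float))
    if res.stderr > 0:
        f = float(res.slope**2 / res.stderr**2)
    else:  # residual variance 0: flat series (F = 0) or exact line (F -> inf)
        f = 0.0 if res.slope == 0 else float("inf")
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0 if res.slope == 0 else 0.0
    return CaptureRateResult(
        bin_s=float(bin_s),
        counts=tuple(int(c) for c in counts),
        mean_per_bin=float(counts.mean()),
        se_per_bin=float(counts.std(ddof=1) / math.sqrt(n_bins)),
        min_count=int(counts.min()),
        max_count=int(counts.max()),
        slope=float(res.slope),
        f_stat=f,
        df=(1, n_bins - 2),
        p_value=p,
        last_bin_coverage=float((duration - (n_bins - 1) * bin_s) / bin_s),
    )
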
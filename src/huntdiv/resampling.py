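"""Shared container for Monte-Carlo / permutation test results."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ResamplingResult", "nearest_rank"]


def nearest_rank(samples: np.ndarray, q: float) -> float:
    """Nearest-rank (inverted CDF) percentile, q in [0, 100]."""
    return float(np.quantile(np.asarray(samples), q / 100.0, method="inverted_cdf"))


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic against a simulated null distribution.

    ``p_value`` uses the add-one convention (b+1)/(m+1) where b counts null
    replicates at least as extreme as the observed value, so p is never 0.
    """

    observed: float
    null_mean: float
    lo_2_5: float
    hi_97_5: float
    p_value: float
    replicates: int
    seed: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def upper_tail_result(
    observed: float, null_samples: np.ndarray, seed: int | None
) -> ResamplingResult:
    """Summarize an upper-tail test: p = Pr(null >= observed), add-one corrected."""
    null_samples = np.asarray(null_samples, dtype=float)
    m = len(null_samples)
    b = int(np.sum(null_samples >= observed))
    return ResamplingResult(
        observed=float(observed),
        null_mean=float(null_samples.mean()),
        lo_2_5=nearest_rank(null_samples, 2.5),
        hi_97_5=nearest_rank(null_samples, 97.5),
        p_value=(b + 1) / (m + 1),
        replicates=m,
        seed=seed,
    )
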
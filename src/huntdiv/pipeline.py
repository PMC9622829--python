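"""One-call orchestration of the full hunt analysis.

Runs, in order: data summary -> subgroup segmentation over a threshold grid
-> equal-access null model -> sequence-length statistics -> attack-order
tests per segmentation -> prey-division statistics, and assembles a single
JSON-serializable report.  Every stochastic result records its seed and
replicate count, so a report can be reproduced exactly from its own
provenance block.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .access import newly_arrived_vs_present, presence_schedule, simulate_access_null
from .division import (
    capture_efficiency_test,
    capture_rate_series,
    rank_correlation,
    share_curve,
    tally,
    top_share,
    uniformity_test,
)
from .events import Hunt, summarize
from .morpho import aggregate_measurements, read_morphometrics
from .order import aba_permutation_test, gap_null_bands, identity_order
from .seqlen import fit_geometric, stratified_variance_permutation_test, termination_trend_test
from .seqlen import assign_strata  # noqa: F401  (re-exported for report consumers)
from .events import derive_dash_sequences
from .subgroups import group_count_profile, segment_hunt

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    h_grid: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    strata: int = 4
    min_sequences: int = 5
    access_replicates: int = 10**6
    permutation_replicates: int = 10**4
    efficiency_replicates: int = 10**4
    gap_cap: int = 40
    capture_bin_s: float = 60.0
    seed: int | None = None
    fast: bool = False

    def effective(self, replicates: int) -> int:
        # --fast scales every Monte-Carlo down 100x for smoke runs
        return max(100, replicates // 100) if self.fast else replicates


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return obj


def run_full_analysis(
    hunt: Hunt,
    config: AnalysisConfig | None = None,
    morphometrics_path: str | Path | None = None,
) -> dict:
    cfg = config or AnalysisConfig()
    seed = cfg.seed

    report: dict = {
        "provenance": {
            "package": "huntdiv",
            "version": __version__,
            "seed": seed,
            "fast": cfg.fast,
            "config": _asdict(cfg),
        },
        "summary": _asdict(summarize(hunt)),
    }

    report["group_count_profile"] = {
        str(h): n for h, n in group_count_profile(hunt, cfg.h_grid).items()
    }

    lengths = [s.length for s in derive_dash_sequences(hunt)]
    report["sequence_lengths"] = {
        "geometric_fit": _asdict(fit_geometric(lengths)),
        "trend_test": _asdict(termination_trend_test(hunt, cfg.strata)),
        "variance_permutation_test": _asdict(
            stratified_variance_permutation_test(
                hunt,
                k=cfg.strata,
                min_sequences=cfg.min_sequences,
                replicates=cfg.effective(cfg.permutation_replicates),
                seed=seed,
            )
        ),
    }

    order = identity_order(hunt)
    per_threshold = {}
    for h in cfg.h_grid:
        groups = segment_hunt(hunt, h)
        schedule = presence_schedule(hunt, groups)
        entry = {
            "n_groups": groups.n_groups,
            "groups": [list(g) for g in groups.groups],
            "epoch_starts": list(groups.epoch_starts),
            "access_expectations": [
                _asdict(a)
                for a in simulate_access_null(
                    hunt, schedule, replicates=cfg.effective(cfg.access_replicates), seed=seed
                )
            ],
            "newly_arrived": [
                _asdict(g)
                for g in newly_arrived_vs_present(
                    hunt,
                    groups,
                    schedule,
                    replicates=cfg.effective(cfg.access_replicates),
                    seed=seed,
                )
            ],
            "aba_test": _asdict(
                aba_permutation_test(
                    order, groups, replicates=cfg.effective(cfg.permutation_replicates), seed=seed
                )
            ),
            "gap_histogram": _asdict(
                gap_null_bands(
                    order,
                    groups,
                    cap=cfg.gap_cap,
                    replicates=cfg.effective(cfg.permutation_replicates),
                    seed=seed,
                )
            ),
        }
        tallies = tally(hunt, groups)
        division: dict = {
            "tallies": [
                {**_asdict(t), "capture_efficiency": t.capture_efficiency} for t in tallies
            ],
            "efficiency_test": _asdict(
                capture_efficiency_test(
                    tallies, replicates=cfg.effective(cfg.efficiency_replicates), seed=seed
                )
            ),
            "per_subgroup": {},
        }
        if any(t.n_captures for t in tallies):
            division["share_curve"] = _asdict(share_curve(tallies))
            division["top50_share_pct"] = top_share(tallies, 0.5)
        for g in range(groups.n_groups):
            rows = [t for t in tallies if t.subgroup == g]
            sub: dict = {"n": len(rows)}
            if len(rows) >= 2:
                sub["uniformity"] = _asdict(uniformity_test([t.n_sequences for t in rows]))
            if len(rows) >= 3:
                sub["spearman"] = _asdict(
                    rank_correlation(
                        [t.n_sequences for t in rows], [t.n_captures for t in rows]
                    )
                )
            if any(t.n_captures for t in rows):
                sub["top50_share_pct"] = top_share(rows, 0.5)
            division["per_subgroup"][str(g + 1)] = sub
        entry["division"] = division
        per_threshold[str(h)] = entry
    report["per_threshold"] = per_threshold

    report["capture_rate"] = _asdict(capture_rate_series(hunt, bin_s=cfg.capture_bin_s))

    if morphometrics_path is not None:
        measurements = read_morphometrics(morphometrics_path)
        report["morphometrics"] = {
            "individuals": [
                {
                    "individual_id": m.individual_id,
                    "efl_cm": m.efl_cm,
                    "efl_sd_cm": m.efl_sd_cm,
                    "weight_kg": m.weight_kg,
                }
                for m in measurements
            ],
            "cohort": _asdict(aggregate_measurements(measurements)),
        }

    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
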
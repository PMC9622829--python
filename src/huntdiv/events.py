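"""Core data model for a recorded group hunt.

A hunt is an ordered log of *dashes* — single high-speed attack passes through
the prey school by an individually identified predator, each scored with a
capture outcome.  A *dash sequence* is a maximal run of consecutive dashes by
the same individual; it ends the moment a different individual attacks.  The
sequence, not the dash, is the unit of turn-taking that every downstream
analysis operates on.

Event logs are plain delimited text with header columns
``time_s,individual,capture`` (capture encoded 0/1).  Times are seconds from
the start of the recording; simultaneous timestamps are allowed and original
row order breaks ties.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DashEvent",
    "DashSequence",
    "Hunt",
    "HuntSummary",
    "HuntFormatError",
    "read_hunt",
    "write_hunt",
    "derive_dash_sequences",
    "truncate",
    "summarize",
]

REQUIRED_COLUMNS = ("time_s", "individual", "capture")


class HuntFormatError(ValueError):
    """Raised when an event log cannot be parsed into a valid hunt."""


@dataclass(frozen=True)
class DashEvent:
    """One dash: an attack pass with a capture outcome."""

    time_s: float
    individual_id: str
    capture: bool

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"time_s must be non-negative, got {self.time_s}")
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")


@dataclass(frozen=True)
class DashSequence:
    """Maximal run of consecutive dashes by one individual.

    ``start_index``/``end_index`` are 0-based, both inclusive, into the
    hunt's event list.
    """

    individual_id: str
    start_index: int
    end_index: int
    captures: int

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("end_index < start_index")
        if self.captures > self.length:
            raise ValueError("captures exceed sequence length")


@dataclass
class Hunt:
    """An ordered dash-event log with recording metadata.

    Events are stored column-wise in numpy arrays for speed; use
    :meth:`events` for a row-wise dataclass view.
    """

    time_s: np.ndarray
    individual_id: np.ndarray
    capture: np.ndarray
    duration_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.capture = np.asarray(self.capture, dtype=bool)
        n = len(self.time_s)
        if not (len(self.individual_id) == len(self.capture) == n):
            raise ValueError("event columns have unequal lengths")
        if n == 0:
            raise HuntFormatError("no events")
        if np.any(self.time_s < 0):
            raise ValueError("negative event times")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("events not in non-decreasing time order")
        if any(not i for i in self.individual_id):
            raise ValueError("empty individual_id")
        if self.duration_s < self.time_s[-1]:
            self.duration_s = float(self.time_s[-1])

    @property
    def n_events(self) -> int:
        return len(self.time_s)

    @property
    def individuals(self) -> list[str]:
        """Distinct individual IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for i in self.individual_id:
            seen.setdefault(i)
        return list(seen)

    def events(self) -> list[DashEvent]:
        return [
            DashEvent(float(t), str(i), bool(c))
            for t, i, c in zip(self.time_s, self.individual_id, self.capture)
        ]

    @classmethod
    def from_events(
        cls,
        events: Iterable[DashEvent],
        duration_s: float | None = None,
        metadata: dict | None = None,
    ) -> "Hunt":
        ev = list(events)
        if not ev:
            raise HuntFormatError("no events")
        times = np.array([e.time_s for e in ev], dtype=float)
        order = np.argsort(times, kind="stable")
        return cls(
            time_s=times[order],
            individual_id=np.array([ev[i].individual_id for i in order], dtype=object),
            capture=np.array([ev[i].capture for i in order], dtype=bool),
            duration_s=float(duration_s) if duration_s is not None else float(times.max()),
            metadata=dict(metadata or {}),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "individual": self.individual_id,
                "capture": self.capture.astype(int),
            }
        )


def read_hunt(path: str | Path, delimiter: str = ",") -> Hunt:
    """Read an event log.

    The file must have header columns ``time_s``, ``individual`` and
    ``capture`` (0/1).  Events are returned sorted by time with a stable
    sort, so coincident timestamps keep file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise HuntFormatError(f"{path}: no events") from None
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise HuntFormatError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise HuntFormatError(f"{path}: no events")

    times = np.empty(len(df), dtype=float)
    caps = np.empty(len(df), dtype=bool)
    for row, (t_raw, c_raw) in enumerate(zip(df["time_s"], df["capture"])):
        line = row + 2  # 1-based, after header
        try:
            times[row] = float(t_raw)
        except (TypeError, ValueError):
            raise HuntFormatError(f"{path}, line {line}: unparseable time {t_raw!r}") from None
        if str(c_raw).strip() in {"0", "1"}:
            caps[row] = str(c_raw).strip() == "1"
        else:
            raise HuntFormatError(f"{path}, line {line}: capture must be 0 or 1, got {c_raw!r}")
        if not isinstance(df["individual"].iloc[row], str) or not df["individual"].iloc[row].strip():
            raise HuntFormatError(f"{path}, line {line}: empty individual id")

    ids = np.array([s.strip() for s in df["individual"]], dtype=object)
    order = np.argsort(times, kind="stable")
    return Hunt(
        time_s=times[order],
        individual_id=ids[order],
        capture=caps[order],
        duration_s=float(times.max()),
    )


def write_hunt(hunt: Hunt, path: str | Path, delimiter: str = ",") -> None:
    """Write the event table in the canonical dialect (round-trips read_hunt)."""
    hunt.to_frame().to_csv(path, sep=delimiter, index=False)


def derive_dash_sequences(hunt: Hunt, max_gap_s: float | None = None) -> list[DashSequence]:
    """Run-length encode the event log into maximal same-individual runs.

    A sequence is defined purely by interruption — a different individual
    attacking — never by elapsed time.  ``max_gap_s``, off by default,
    additionally splits a run when consecutive dashes are separated by more
    than that many seconds.
    """
    ids = hunt.individual_id
    n = hunt.n_events
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] = ids[1:] != ids[:-1]
        if max_gap_s is not None:
            breaks[1:] |= np.diff(hunt.time_s) > max_gap_s
    starts = np.flatnonzero(breaks)
    ends = np.append(starts[1:], n) - 1
    cap_cum = np.concatenate([[0], np.cumsum(hunt.capture)])
    return [
        DashSequence(
            individual_id=str(ids[s]),
            start_index=int(s),
            end_index=int(e),
            captures=int(cap_cum[e + 1] - cap_cum[s]),
        )
        for s, e in zip(starts, ends)
    ]


def truncate(hunt: Hunt, cutoff_s: float) -> Hunt:
    """Keep events with ``time_s <= cutoff_s``; sequences are re-derived.

    A dash sequence straddling the cutoff is cut at the last retained dash.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    keep = hunt.time_s <= cutoff_s
    if not keep.any():
        raise ValueError("empty truncation: cutoff precedes first event")
    return Hunt(
        time_s=hunt.time_s[keep],
        individual_id=hunt.individual_id[keep],
        capture=hunt.capture[keep],
        duration_s=min(hunt.duration_s, float(cutoff_s)),
        metadata=dict(hunt.metadata),
    )


@dataclass(frozen=True)
class HuntSummary:
    n_individuals: int
    n_dashes: int
    n_sequences: int
    n_captures: int
    mean_sequence_length: float
    se_sequence_length: float
    max_sequence_length: int
    se_defined: bool = True

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=2)


def summarize(hunt: Hunt) -> HuntSummary:
    """Counts plus mean ± SE of dash-sequence length.

    SE is the sample standard deviation (n−1) over sqrt(n_sequences); with a
    single sequence it is undefined and reported as 0 with ``se_defined``
    False.
    """
    seqs = derive_dash_sequences(hunt)
    lengths = np.array([s.length for s in seqs], dtype=float)
    n = len(lengths)
    se_defined = n >= 2
    se = float(lengths.std(ddof=1) / math.sqrt(n)) if se_defined else 0.0
    return HuntSummary(
        n_individuals=len(hunt.individuals),
        n_dashes=hunt.n_events,
        n_sequences=n,
        n_captures=int(hunt.capture.sum()),
        mean_sequence_length=float(lengths.mean()),
        se_sequence_length=se,
        max_sequence_length=int(lengths.max()),
        se_defined=se_defined,
    )
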
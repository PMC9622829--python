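"""Shared builders for test hunts."""

from __future__ import annotations

import numpy as np

from huntdiv.events import Hunt


def hunt_from_ids(ids, captures=None, times=None, duration=None) -> Hunt:
    """Build a hunt from a list of per-dash individual IDs.

    Times default to 0, 1, 2, ... seconds; captures default to all False.
    """
    n = len(ids)
    if times is None:
        times = np.arange(n, dtype=float)
    if captures is None:
        captures = np.zeros(n, dtype=bool)
    return Hunt(
        time_s=np.asarray(times, dtype=float),
        individual_id=np.asarray(list(ids), dtype=object),
        capture=np.asarray(captures, dtype=bool),
        duration_s=float(duration) if duration is not None else float(np.max(times)),
    )


def brute_force_rle(ids):
    """Independent run-length encoding oracle."""
    runs = []
    for x in ids:
        if runs and runs[-1][0] == x:
            runs[-1][1] += 1
        else:
            runs.append([x, 1])
    return [(x, n) for x, n in runs]


def brute_force_aba(order):
    """Triple-enumeration oracle for ABA patterns."""
    order = list(order)
    return sum(
        1
        for j in range(len(order) - 2)
        if order[j] == order[j + 2] and order[j] != order[j + 1]
    )
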
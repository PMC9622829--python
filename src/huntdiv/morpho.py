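"""Calibrated length measurement and length-weight allometry for billfish.

Lengths are measured as eye-fork length (EFL) from still frames: a pixel
distance is converted to cm by the ratio of a reference object's known
length to its pixel length in the same frame.  Weight follows the standard
allometric power law W = a * EFL^b with the striped-marlin coefficients
a = 1.33263e-6 and b = 3.41344 (EFL in cm, W in kg).

Repeated measurements per individual (typically 6 frames) are aggregated to
a mean EFL with its SD; weight is computed once from the mean EFL, not
averaged over per-frame weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ALLOMETRY_A",
    "ALLOMETRY_B",
    "MorphMeasurement",
    "CohortSummary",
    "calibrate_length",
    "efl_to_weight",
    "aggregate_measurements",
    "read_morphometrics",
]

ALLOMETRY_A = 0.00000133263
ALLOMETRY_B = 3.41344

MORPH_COLUMNS = ("individual", "frame", "pixel_len", "ref_pixel_len", "ref_cm")


def calibrate_length(pixel_len: float, ref_pixel_len: float, ref_cm: float) -> float:
    """Pixel distance to cm via a same-frame reference of known length."""
    if pixel_len <= 0 or ref_pixel_len <= 0 or ref_cm <= 0:
        raise ValueError("all calibration inputs must be positive")
    return pixel_len * ref_cm / ref_pixel_len


def efl_to_weight(efl_cm: float) -> float:
    """Allometric weight (kg) from eye-fork length (cm); strictly increasing."""
    if efl_cm < 0:
        raise ValueError("EFL must be non-negative")
    return ALLOMETRY_A * efl_cm**ALLOMETRY_B


@dataclass(frozen=True)
class MorphMeasurement:
    """Repeated calibrated lengths for one individual."""

    individual_id: str
    efl_cm_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.efl_cm_values:
            raise ValueError("at least one measurement required")
        if any(v <= 0 for v in self.efl_cm_values):
            raise ValueError("EFL values must be positive")

    @property
    def efl_cm(self) -> float:
        return float(np.mean(self.efl_cm_values))

    @property
    def efl_sd_cm(self) -> float:
        v = np.asarray(self.efl_cm_values)
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    @property
    def weight_kg(self) -> float:
        return efl_to_weight(self.efl_cm)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_efl_cm: float
    sd_efl_cm: float
    min_efl_cm: float
    max_efl_cm: float
    mean_weight_kg: float
    sd_weight_kg: float
    min_weight_kg: float
    max_weight_kg: float
    mean_measurement_sd_cm: float

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps({k: round(v, 1) if isinstance(v, float) else v for k, v in asdict(self).items()}, indent=2)


def aggregate_measurements(measurements) -> CohortSummary:
    """Cohort summary over per-individual mean EFLs and derived weights."""
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements")
    efl = np.array([m.efl_cm for m in ms])
    w = np.array([m.weight_kg for m in ms])
    sd = 0.0 if len(efl) < 2 else float(efl.std(ddof=1))
    sdw = 0.0 if len(w) < 2 else float(w.std(ddof=1))
    return CohortSummary(
        n=len(ms),
        mean_efl_cm=float(efl.mean()),
        sd_efl_cm=sd,
        min_efl_cm=float(efl.min()),
        max_efl_cm=float(efl.max()),
        mean_weight_kg=float(w.mean()),
        sd_weight_kg=sdw,
        min_weight_kg=float(w.min()),
        max_weight_kg=float(w.max()),
        mean_measurement_sd_cm=float(np.mean([m.efl_sd_cm for m in ms])),
    )


def read_morphometrics(path: str | Path) -> list[MorphMeasurement]:
    """Read the morphometrics CSV: individual,frame,pixel_len,ref_pixel_len,ref_cm."""
    df = pd.read_csv(path)
    for col in MORPH_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    out = []
    for ind, sub in df.groupby("individual", sort=True):
        efl = [
            calibrate_length(row.pixel_len, row.ref_pixel_len, row.ref_cm)
            for row in sub.itertuples()
        ]
        out.append(MorphMeasurement(individual_id=str(ind), efl_cm_values=tuple(efl)))
    return out
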
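"""Deviation statistics and unit conversions for accuracy benchmarking.

Values are kept at full precision; presentation rounding (3 decimals for eV,
4 for TEDM/f, 1 for nm) happens only in formatted output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import EV_NM, HARTREE_EV
from .errors import ArgumentError


@dataclass(eq=False)
class DeviationTable:
    """1B/2B excitation energies against a reference series, with per-label
    deviations and mean unsigned deviations (MUD)."""

    frame: pd.DataFrame
    mud1: float
    mud2: float

    def __str__(self) -> str:  # presentation: 3 decimals, matching eV tables
        body = self.frame.round(3).to_string(index=False)
        return f"{body}\nMUD(1B)={self.mud1:.3f}  MUD(2B)={self.mud2:.3f}"


def deviation_table(
    labels: Sequence,
    series_1b: Sequence[float],
    series_2b: Sequence[float],
    series_ref: Sequence[float],
) -> DeviationTable:
    """dev1 = 1B − ref, dev2 = 2B − ref, MUDs as means of |dev|."""
    n = len(labels)
    if not (n == len(series_1b) == len(series_2b) == len(series_ref)) or n < 1:
        raise ArgumentError("deviation_table needs equal-length non-empty series")
    s1 = np.asarray(series_1b, dtype=float)
    s2 = np.asarray(series_2b, dtype=float)
    ref = np.asarray(series_ref, dtype=float)
    frame = pd.DataFrame(
        {
            "label": list(labels),
            "omega_1b_eV": s1,
            "omega_2b_eV": s2,
            "omega_ref_eV": ref,
            "dev1_eV": s1 - ref,
            "dev2_eV": s2 - ref,
        }
    )
    return DeviationTable(
        frame=frame,
        mud1=mean_unsigned(s1 - ref),
        mud2=mean_unsigned(s2 - ref),
    )


def mean_unsigned(values: Sequence[float]) -> float:
    """Mean of absolute values (MUD/MUE)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ArgumentError("mean_unsigned of an empty series")
    return float(np.mean(np.abs(arr)))


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation; affine-invariant in either series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ArgumentError("r_squared needs two equal-length series, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ArgumentError("r_squared undefined for zero-variance input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def ev_to_nm(e: float) -> float:
    """Photon wavelength (nm) for an energy in eV."""
    if e <= 0:
        raise ArgumentError(f"energy must be positive for nm conversion, got {e}")
    return EV_NM / e


def ev_to_hartree(e: float) -> float:
    return e / HARTREE_EV
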
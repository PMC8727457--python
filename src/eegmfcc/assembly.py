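"""Fragment combination formulas.

Every excited-state property P of the complex is assembled from a one-body
(chromophore-only) value and two-body corrections:

    P = P_m + Σ_j (P_mj − P_m)        (excitation energy, TEDM, atomic forces)

with j running over residues whose closest approach to the chromophore is
within the two-body threshold. For a chromophore covalently bonded into the
chain, the one-body part is replaced by the local capped-fragment combination
Σω(capped) − Σω(concap). The ground-state total energy combines capped
residues, concap deductions, distant-pair corrections and an MM double-counting
term:

    E = Σ_i Ẽ(cap*_{i−1} A_i cap_{i+1}) − Σ_i Ẽ(cap*_i cap_{i+1})
        + Σ_{distant pairs} (Ẽ_ij − Ẽ_i − Ẽ_j) − E_dc

The oscillator strength is f = (2/3) ω |μ|² in atomic units (ω converted
eV → hartree before use).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import EV_NM, HARTREE_EV
from .errors import (
    AlignmentError,
    ArgumentError,
    CompletenessError,
    ProvenanceError,
)


@dataclass(eq=False)
class AssemblyReport:
    """Assembled excited-state properties plus per-residue provenance."""

    omega_1b: float
    pair_corrections: dict[int, float] = field(default_factory=dict)
    omega_assembled: float | None = None
    tedm_assembled: np.ndarray | None = None
    oscillator_strength: float | None = None
    forces_assembled: np.ndarray | None = None
    lambda_2b: float | None = None
    embedding: bool = True
    bonded: bool = False

    def __post_init__(self) -> None:
        if self.omega_assembled is None:
            self.omega_assembled = self.omega_1b + math.fsum(
                self.pair_corrections.values()
            )
        if self.oscillator_strength is not None and self.oscillator_strength < 0:
            raise ArgumentError("oscillator strength cannot be negative")

    def to_dict(self) -> dict:
        return {
            "omega_assembled_ev": self.omega_assembled,
            "omega_1b_ev": self.omega_1b,
            "pair_corrections_ev": {str(k): v for k, v in self.pair_corrections.items()},
            "tedm_au": None
            if self.tedm_assembled is None
            else list(self.tedm_assembled),
            "oscillator_strength": self.oscillator_strength,
            "forces_hartree_bohr": None
            if self.forces_assembled is None
            else self.forces_assembled.tolist(),
            "lambda_2b": self.lambda_2b,
            "embedding": self.embedding,
            "bonded": self.bonded,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


# ---------------------------------------------------------------------------
# Ground state
# ---------------------------------------------------------------------------


def ground_state_energy(
    capped: Mapping[object, float] | Sequence[float],
    concaps: Mapping[object, float] | Sequence[float],
    pair_results: Mapping[object, tuple[float, float, float]]
    | Sequence[tuple[float, float, float]],
    e_dc: float,
    expected_capped: Sequence[object] | None = None,
    expected_concaps: Sequence[object] | None = None,
) -> float:
    """Σ capped − Σ concaps + Σ (Ẽij − Ẽi − Ẽj) − E_dc, in hartree.

    ``expected_*`` label lists, when given, make missing fragment results a
    :class:`CompletenessError` instead of a silent omission.
    """
    capped_map = capped if isinstance(capped, Mapping) else dict(enumerate(capped))
    concap_map = concaps if isinstance(concaps, Mapping) else dict(enumerate(concaps))
    for expected, got, kind in (
        (expected_capped, capped_map, "capped-residue"),
        (expected_concaps, concap_map, "concap"),
    ):
        if expected is not None:
            absent = [str(k) for k in expected if k not in got]
            if absent:
                raise CompletenessError(f"missing {kind} results: {absent}")
    pair_vals = (
        pair_results.values() if isinstance(pair_results, Mapping) else pair_results
    )
    return (
        math.fsum(capped_map.values())
        - math.fsum(concap_map.values())
        + math.fsum(eij - ei - ej for eij, ei, ej in pair_vals)
        - e_dc
    )


# ---------------------------------------------------------------------------
# Excitation energy
# ---------------------------------------------------------------------------


def excitation_energy_nonbonded(
    omega_m: float, pair_omegas: Mapping[int, float]
) -> tuple[float, AssemblyReport]:
    """ω = ω_m + Σ_j (ω_mj − ω_m) for a non-covalently bound chromophore."""
    corrections = {j: w - omega_m for j, w in pair_omegas.items()}
    report = AssemblyReport(omega_1b=omega_m, pair_corrections=corrections)
    return report.omega_assembled, report


def excitation_energy_bonded(
    capped_omegas: Mapping[int, float],
    concap_omegas: Mapping[int, float],
    pair_omegas: Mapping[int, float],
    omega_m: float,
) -> float:
    """Local three-capped-fragment combination plus distant 2B corrections,
    for a chromophore covalently embedded in the chain.

    ``capped_omegas`` holds ω for the capped fragments i = m−1..m+1,
    ``concap_omegas`` for the concaps i = m−1..m; ``pair_omegas`` covers
    residues outside the [m−2, m+2] window.
    """
    if len(capped_omegas) != 3 or len(concap_omegas) != 2:
        raise CompletenessError(
            "bonded assembly needs 3 capped-fragment and 2 concap omegas; got "
            f"{sorted(capped_omegas)} / {sorted(concap_omegas)}"
        )
    local = math.fsum(capped_omegas.values()) - math.fsum(concap_omegas.values())
    return local + math.fsum(w - omega_m for w in pair_omegas.values())


# ---------------------------------------------------------------------------
# TEDM, oscillator strength, forces
# ---------------------------------------------------------------------------


def assemble_tedm(
    mu_m: np.ndarray, pair_mus: Mapping[int, np.ndarray]
) -> np.ndarray:
    """Componentwise μ = μ_m + Σ_j (μ_mj − μ_m), atomic units."""
    mu_m = np.asarray(mu_m, dtype=float).reshape(3)
    out = mu_m.copy()
    for mu in pair_mus.values():
        out = out + (np.asarray(mu, dtype=float).reshape(3) - mu_m)
    return out


def oscillator_strength(omega_ev: float, mu: np.ndarray) -> float:
    """f = (2/3) ω |μ|² in atomic units; ω converted eV → hartree."""
    if omega_ev <= 0:
        raise ArgumentError(f"excitation energy must be positive, got {omega_ev}")
    mu = np.asarray(mu, dtype=float).reshape(3)
    return (2.0 / 3.0) * (omega_ev / HARTREE_EV) * float(np.dot(mu, mu))


def assemble_forces(
    f_m: np.ndarray, pair_fs: Mapping[int, np.ndarray]
) -> np.ndarray:
    """Per-atom, per-component F = F_m + Σ_j (F_mj − F_m), hartree/bohr.

    All arrays must share the chromophore-atom ordering of ``f_m``.
    """
    f_m = np.asarray(f_m, dtype=float)
    if f_m.ndim != 2 or f_m.shape[1] != 3:
        raise AlignmentError(f"forces must be (n_atoms, 3); got {f_m.shape}")
    out = f_m.copy()
    for j, fj in pair_fs.items():
        fj = np.asarray(fj, dtype=float)
        if fj.shape != f_m.shape:
            raise AlignmentError(
                f"pair {j}: force array {fj.shape} does not match {f_m.shape}"
            )
        out = out + (fj - f_m)
    return out


# ---------------------------------------------------------------------------
# Per-residue decomposition (embedding-free scheme)
# ---------------------------------------------------------------------------

DECOMPOSITION_COLUMNS = ["residue", "omega_mj_eV", "dEx_meV", "dWL_nm", "shift_direction"]


def decompose_per_residue(
    omega_m: float,
    pair_omegas: Mapping[int, float],
    embedded: bool = False,
    names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-residue spectral-shift table from embedding-free two-body energies.

    ΔEx_j = (ω_mj − ω_m) in meV; ΔWL_j the matching wavelength change in nm.
    Positive ΔEx is a blue shift, negative a red shift. Electrostatically
    embedded inputs are refused: the background field mixes many-body effects
    into each pair and obscures the individual contribution.
    """
    if embedded:
        raise ProvenanceError(
            "per-residue decomposition requires embedding-free (GMFCC) pair "
            "energies; got electrostatically embedded inputs"
        )
    if omega_m <= 0:
        raise ArgumentError("omega_m must be positive for wavelength conversion")
    rows = []
    for j in sorted(pair_omegas):
        w = pair_omegas[j]
        dex_mev = (w - omega_m) * 1000.0
        dwl_nm = EV_NM / w - EV_NM / omega_m
        direction = "blue" if dex_mev > 0 else ("red" if dex_mev < 0 else "none")
        rows.append(
            {
                "residue": names[j] if names else j,
                "omega_mj_eV": w,
                "dEx_meV": dex_mev,
                "dWL_nm": dwl_nm,
                "shift_direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=DECOMPOSITION_COLUMNS)


def snapshot_average(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of ΔEx/ΔWL per residue over snapshot tables.

    Residues absent from a snapshot are averaged over the snapshots where they
    appear (missing means absent, not zero); ``n_snapshots`` reports the count.
    """
    if not len(tables):
        raise ArgumentError("snapshot_average needs at least one table")
    stacked = pd.concat(tables, ignore_index=True)
    grouped = stacked.groupby("residue", sort=False).agg(
        omega_mj_eV=("omega_mj_eV", "mean"),
        dEx_meV=("dEx_meV", "mean"),
        dWL_nm=("dWL_nm", "mean"),
        n_snapshots=("dEx_meV", "size"),
    )
    out = grouped.reset_index()
    out["shift_direction"] = np.where(
        out["dEx_meV"] > 0, "blue", np.where(out["dEx_meV"] < 0, "red", "none")
    )
    return out
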
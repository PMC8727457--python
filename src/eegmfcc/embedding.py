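"""Electrostatic embedding: background point-charge sets and the pairwise
charge-charge double-counting arithmetic.

Charges are elementary-charge units at angstrom coordinates; Coulomb energies
come out in hartree (distances converted to bohr inside the sum only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import BOHR_PER_ANGSTROM
from .errors import (
    ArgumentError,
    ChargeModelError,
    FormatError,
    SingularityError,
    ValidationError,
)
from .fragmentation import FragmentSpec, PairList
from .structure import Atom, MolecularSystem


@dataclass(eq=False)
class PointCharge:
    q: float  # elementary charges
    coords: np.ndarray  # angstrom
    origin_serial: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ArgumentError("point charge needs finite 3-vector coordinates")


@dataclass(eq=False)
class ChargeSet:
    """An ordered collection of point charges plus a log of atoms deliberately
    left out (the link-replaced bond partners)."""

    charges: list[PointCharge] = field(default_factory=list)
    excluded_atoms: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.charges)

    def coords(self) -> np.ndarray:
        return np.array([c.coords for c in self.charges]).reshape(-1, 3)

    def q(self) -> np.ndarray:
        return np.array([c.q for c in self.charges])

    @property
    def total_charge(self) -> float:
        return float(sum(c.q for c in self.charges))


class ChargeModel:
    """Resolves every system atom to one point charge.

    Two modes mirror the two charge schemes a practitioner feeds in:
    force-field-style templates keyed by (residue name, atom name), and
    per-structure (ESP-style) charges keyed by atom serial.
    """

    def __init__(
        self,
        templates: dict[tuple[str, str], float] | None = None,
        per_atom: dict[int, float] | None = None,
        provenance: str | None = None,
    ) -> None:
        if (templates is None) == (per_atom is None):
            raise ArgumentError("pass exactly one of templates / per_atom")
        self.templates = templates
        self.per_atom = per_atom
        self.provenance = provenance or (
            "template" if templates is not None else "per_atom"
        )

    def charge_for(self, atom: Atom, residue_name: str) -> float:
        if self.templates is not None:
            key = (residue_name, atom.name)
            if key not in self.templates:
                raise ChargeModelError(
                    f"no charge for atom {atom.name!r} of residue {residue_name!r}"
                )
            return self.templates[key]
        assert self.per_atom is not None
        if atom.serial not in self.per_atom:
            raise ChargeModelError(f"no charge for atom serial {atom.serial}")
        return self.per_atom[atom.serial]

    def validate(self, system: MolecularSystem) -> None:
        """Check full resolution and, for templates, integral residue totals."""
        for r in system.residues:
            total = 0.0
            for a in r.atoms:
                total += self.charge_for(a, r.name)
            if self.templates is not None and abs(total - round(total)) > 1e-6:
                raise ValidationError(
                    f"residue template {r.name!r} total charge {total:.6f} "
                    "is not integral"
                )


def residue_charges(
    system: MolecularSystem, indices: Iterable[int], model: ChargeModel
) -> ChargeSet:
    """One point charge per atom of the listed residues."""
    cs = ChargeSet()
    for i in indices:
        r = system.residue(i)
        for a in r.atoms:
            cs.charges.append(PointCharge(model.charge_for(a, r.name), a.coords, a.serial))
    return cs


def background_charges(
    system: MolecularSystem, fragment: FragmentSpec, model: ChargeModel
) -> ChargeSet:
    """Point charges for everything outside the fragment's QM region.

    Atoms replaced by link hydrogens (the removed bond partners) are excluded
    outright — their charge is dropped, not redistributed — and logged.
    """
    qm = fragment.source_serials()
    removed = fragment.removed_serials()
    cs = ChargeSet()
    for r in system.residues:
        for a in r.atoms:
            if a.serial in qm:
                continue
            if a.serial in removed:
                cs.excluded_atoms.append(
                    {
                        "serial": a.serial,
                        "name": a.name,
                        "residue": a.residue_index,
                        "reason": "replaced by link hydrogen",
                    }
                )
                continue
            cs.charges.append(
                PointCharge(model.charge_for(a, r.name), a.coords, a.serial)
            )
    return cs


def coulomb_energy(
    set_a: ChargeSet | Sequence[PointCharge], set_b: ChargeSet | Sequence[PointCharge]
) -> float:
    """Sum of q_a q_b / r_ab (hartree; r converted angstrom -> bohr)."""
    a = set_a if isinstance(set_a, ChargeSet) else ChargeSet(list(set_a))
    b = set_b if isinstance(set_b, ChargeSet) else ChargeSet(list(set_b))
    if len(a) == 0 or len(b) == 0:
        return 0.0
    r = cdist(a.coords(), b.coords()) * BOHR_PER_ANGSTROM
    if np.any(r < 1e-10):
        raise SingularityError("coincident charges in Coulomb sum")
    return float(np.sum(np.outer(a.q(), b.q()) / r))


def double_counting_correction(
    system: MolecularSystem, ground_pairs: PairList, model: ChargeModel
) -> float:
    """MM-level Coulomb interaction summed over the given residue pairs
    (hartree). Which pair set is actually doubly counted is the caller's
    decision; this operation is pure arithmetic over the list it receives."""
    total = 0.0
    for i, j in ground_pairs:
        total += coulomb_energy(
            residue_charges(system, [i], model), residue_charges(system, [j], model)
        )
    return total


# ---------------------------------------------------------------------------
# Text interchange
# ---------------------------------------------------------------------------


def load_charge_table(path: str | Path) -> ChargeModel:
    """Read a whitespace-separated charge table.

    Three columns ``residue_name atom_name charge`` load as a force-field-style
    template; two columns ``serial charge`` load as per-atom (ESP-style)
    charges. Lines starting with ``#`` are comments.
    """
    path = Path(path)
    templates: dict[tuple[str, str], float] = {}
    per_atom: dict[int, float] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        try:
            if len(cols) == 3:
                templates[(cols[0], cols[1])] = float(cols[2])
            elif len(cols) == 2:
                per_atom[int(cols[0])] = float(cols[1])
            else:
                raise ValueError("expected 2 or 3 columns")
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: bad charge-table line {raw!r}") from exc
    if templates and per_atom:
        raise FormatError(f"{path}: mixed template and per-atom rows")
    if not templates and not per_atom:
        raise FormatError(f"{path}: no charge rows")
    if templates:
        return ChargeModel(templates=templates, provenance="template")
    return ChargeModel(per_atom=per_atom, provenance="per_atom")


def write_charge_table(model: ChargeModel, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    if model.templates is not None:
        for (res, atom), q in model.templates.items():
            lines.append(f"{res:<6s} {atom:<6s} {q:12.6f}")
    else:
        assert model.per_atom is not None
        for serial, q in model.per_atom.items():
            lines.append(f"{serial:>8d} {q:12.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_charges(charges: ChargeSet, path: str | Path) -> Path:
    """Serialize background charges as ``x y z q`` lines (angstrom, e)."""
    path = Path(path)
    lines = [
        f"{c.coords[0]:18.8f} {c.coords[1]:18.8f} {c.coords[2]:18.8f} {c.q:12.6f}"
        for c in charges.charges
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_charges(path: str | Path) -> ChargeSet:
    path = Path(path)
    cs = ChargeSet()
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 4:
            raise FormatError(f"{path}:{ln}: expected 'x y z q'")
        cs.charges.append(
            PointCharge(float(cols[3]), np.array([float(c) for c in cols[:3]]))
        )
    return cs
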
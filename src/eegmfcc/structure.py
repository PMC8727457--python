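"""Structure data model, PDB I/O and inter-residue distance queries.

The model is deliberately small: ordered residues, each holding ordered atoms,
with a 1-based *global* residue index that runs through the chains in file
order. That global index is the unit index used by every fragmentation sum.
Coordinates are angstrom throughout this layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    AmbiguityError,
    ArgumentError,
    FormatError,
    ResidueLookupError,
    StructureError,
)

#: Residue codes treated as standard nucleotides (RNA and DNA).
STANDARD_NUCLEOTIDES = frozenset(
    {"A", "G", "C", "U", "DA", "DG", "DC", "DT", "DU", "I", "DI"}
)

#: PDB dialects disagree on primes; cut-site atoms are normalized on input.
NAME_NORMALIZATION = {"C3": "C3'", "C3*": "C3'", "O3": "O3'", "O3*": "O3'"}

NUCLEOTIDE = "nucleotide"
CHROMOPHORE = "chromophore"
OTHER = "other"


@dataclass(eq=False)
class Atom:
    """A single atom; ``coords`` is a length-3 float array in angstrom."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name}: bad coordinates")
        if not self.element:
            raise StructureError(f"atom {self.serial} {self.name}: empty element")


@dataclass(eq=False)
class Residue:
    """One chain unit: a nucleotide, the chromophore, or anything else."""

    index: int  # 1-based global position in chain-concatenated order
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    role: str = OTHER

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.index} ({self.name}): no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass(eq=False)
class MolecularSystem:
    """Ordered residues with contiguous 1-based global indices."""

    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping ---------------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r.index)
        return out

    def residue(self, i: int) -> Residue:
        if not 1 <= i <= self.N:
            raise ResidueLookupError(f"no residue with index {i} (system has {self.N})")
        return self.residues[i - 1]

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chromophore_indices(self) -> list[int]:
        return [r.index for r in self.residues if r.role == CHROMOPHORE]

    def validate(self) -> None:
        seen_serials: set[int] = set()
        for pos, r in enumerate(self.residues, start=1):
            if r.index != pos:
                raise StructureError(
                    f"residue indices must be contiguous 1..N; got {r.index} at {pos}"
                )
            if not r.atoms:
                raise StructureError(f"residue {r.index} ({r.name}) has no atoms")
            for a in r.atoms:
                if a.serial in seen_serials:
                    raise StructureError(f"duplicate atom serial {a.serial}")
                seen_serials.add(a.serial)
                a.residue_index = r.index

    # -- chain topology ------------------------------------------------------

    def chain_neighbor(self, i: int, step: int) -> int | None:
        """Global index of the backbone neighbor of residue ``i`` (``step`` is
        +1 or -1), or None at a chain end.

        Two consecutive residues of one chain are covalently linked when the
        upstream one carries the C3'/O3' ester bond and the downstream one a
        phosphorus to receive it. A non-covalent ligand (no backbone atoms, or
        its own chain) therefore never has backbone neighbors, while a
        chromophore grafted into the chain does.
        """
        r = self.residue(i)
        j = i + step
        if not 1 <= j <= self.N:
            return None
        other = self.residue(j)
        if other.chain_id != r.chain_id:
            return None
        up, down = (r, other) if step > 0 else (other, r)
        if up.has_atom("C3'") and up.has_atom("O3'") and down.has_atom("P"):
            return j
        return None


def min_distance(
    group_a: Sequence[Atom] | np.ndarray, group_b: Sequence[Atom] | np.ndarray
) -> float:
    """Minimum Euclidean distance (angstrom) over all cross pairs."""
    xa = _as_coords(group_a)
    xb = _as_coords(group_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ArgumentError("min_distance requires two non-empty atom groups")
    return float(cdist(xa, xb).min())


def _as_coords(group: Sequence[Atom] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return group.reshape(-1, 3).astype(float)
    seq = list(group)
    if seq and isinstance(seq[0], Atom):
        return np.array([a.coords for a in seq]).reshape(-1, 3)
    return np.asarray(seq, dtype=float).reshape(-1, 3)


def neighbors_within(system: MolecularSystem, m: int, lam: float) -> list[int]:
    """Indices j != m whose closest approach to residue ``m`` is <= lam (closed
    threshold), ascending. Monotone non-decreasing in lam by construction."""
    if lam < 0 or not math.isfinite(lam) and lam != math.inf:
        raise ArgumentError(f"lambda must be >= 0, got {lam}")
    center = system.residue(m).atoms
    out = []
    for r in system.residues:
        if r.index == m:
            continue
        if lam == math.inf or min_distance(center, r.atoms) <= lam:
            out.append(r.index)
    return out


def select_chromophore(
    system: MolecularSystem, resname: str, chain: str | None = None
) -> MolecularSystem:
    """Flag the (unique) residue named ``resname`` as the chromophore.

    Standard nucleotide codes are (re)assigned the nucleotide role. Multiple
    matches require an explicit ``chain`` qualifier.
    """
    matches = [
        r
        for r in system.residues
        if r.name == resname and (chain is None or r.chain_id == chain)
    ]
    if not matches:
        where = f" in chain {chain}" if chain else ""
        raise ResidueLookupError(f"no residue named {resname!r}{where}")
    if len(matches) > 1:
        chains = sorted({r.chain_id for r in matches})
        raise AmbiguityError(
            f"{len(matches)} residues named {resname!r} (chains {chains}); "
            "pass a chain qualifier"
        )
    for r in system.residues:
        if r is matches[0]:
            r.role = CHROMOPHORE
        elif r.name in STANDARD_NUCLEOTIDES:
            r.role = NUCLEOTIDE
    return system


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed; fixed-column PDB is the contract)
# ---------------------------------------------------------------------------


def read_pdb(path: str | Path) -> MolecularSystem:
    """Read a single-model PDB file into a :class:`MolecularSystem`.

    Residues are ordered by file order within each chain, chains concatenated;
    HETATM ligands are retained; the first alternate conformer wins; C3/C3*
    and O3/O3* are normalized to C3'/O3'.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(l.startswith(("ATOM", "HETATM")) for l in lines):
        first = lines[0] if lines else "<empty file>"
        raise FormatError(f"{path}: no ATOM/HETATM records; first line: {first!r}")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise FormatError(f"{path}: {exc}") from exc

    residues: list[Residue] = []
    idx = 0
    serial = 0
    for chain in st[0]:
        for gres in chain:
            idx += 1
            res = Residue(index=idx, name=gres.name.strip(), chain_id=chain.name)
            seen: dict[str, str] = {}
            for ga in gres:
                name = NAME_NORMALIZATION.get(ga.name, ga.name)
                altloc = ga.altloc or ""
                if name in seen:
                    if altloc == seen[name]:
                        raise StructureError(
                            f"{path}: duplicate atom {name!r} in "
                            f"{chain.name}/{gres.seqid.num} {gres.name}"
                        )
                    continue  # later alternate conformer: first one wins
                seen[name] = altloc
                serial += 1
                res.atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=ga.element.name or "X",
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        residue_index=idx,
                    )
                )
            if res.name in STANDARD_NUCLEOTIDES:
                res.role = NUCLEOTIDE
            residues.append(res)
    return MolecularSystem(residues=residues)


def write_pdb(system: MolecularSystem, path: str | Path) -> Path:
    """Write ``system`` as fixed-column PDB; inverse of :func:`read_pdb` on
    coordinates (3 decimals), names and ordering."""
    if system.N == 0 or system.atom_count == 0:
        raise FormatError("refusing to write an empty system")
    st = gemmi.Structure()
    st.name = "eegmfcc"
    model = gemmi.Model("1")
    for chain_id, indices in system.chains.items():
        chain = gemmi.Chain(chain_id)
        for seq, i in enumerate(indices, start=1):
            r = system.residue(i)
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(seq, " ")
            gres.het_flag = "A" if r.role == NUCLEOTIDE else "H"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path
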
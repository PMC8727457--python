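"""Backbone severing, link-hydrogen capping, and fragment enumeration.

The polymer is cut only at the sugar C3'-O3' ester bond. Following the
convention that the bridging oxygen travels with the *downstream* unit, the
fragmentation unit of nucleotide ``i`` is its residue minus its own O3' (when a
3' successor exists) plus the O3' inherited from residue ``i-1`` (when a 5'
predecessor exists). Every severed bond C3'(i)-O3'(i) then has exactly one end
inside any unit-contiguous fragment, and a hydrogen link atom saturates the
dangling valence:

* the fragment keeps C3'  -> H placed 1.09 angstrom along C3'->O3'
* the fragment keeps O3'  -> H placed 0.96 angstrom along O3'->C3'

The chromophore is never severed; its unit is its residue verbatim.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import (
    ArgumentError,
    GeometryError,
    RangeError,
    ResidueLookupError,
    RoleError,
    StructureError,
)
from .structure import (
    CHROMOPHORE,
    Atom,
    MolecularSystem,
    min_distance,
    neighbors_within,
)


@dataclass(frozen=True)
class LinkAtomRule:
    """Hydrogen-capping rule for one orientation of a severed backbone bond."""

    kept_atom_name: str
    removed_atom_name: str
    h_bond_length: float  # angstrom

    def __post_init__(self) -> None:
        if self.h_bond_length <= 0:
            raise ArgumentError("h_bond_length must be positive")


#: Keep C3' -> cap at 1.09 angstrom; keep O3' -> cap at 0.96 angstrom.
DEFAULT_LINK_RULES = {
    "C3'": LinkAtomRule("C3'", "O3'", 1.09),
    "O3'": LinkAtomRule("O3'", "C3'", 0.96),
}


@dataclass(frozen=True)
class FragmentLabel:
    kind: str  # ONE_BODY | TWO_BODY | CAPPED_RESIDUE | CONCAP | PAIR_GROUND |
    #           MONOMER | TRUNCATED_FULL | CHAIN | FULL_SYSTEM | REGION
    indices: tuple = ()
    threshold: float | None = None

    def __str__(self) -> str:
        parts = ",".join(str(i) for i in self.indices)
        lam = "" if self.threshold is None else f";lam={self.threshold:g}"
        return f"{self.kind}({parts}{lam})"

    def slug(self) -> str:
        parts = "_".join(str(i) for i in self.indices)
        lam = "" if self.threshold is None else f"_lam{self.threshold:g}"
        return f"{self.kind.lower()}_{parts}{lam}".rstrip("_")


@dataclass(eq=False)
class LinkAtom:
    """Provenance of one placed cap: the hydrogen, the kept anchor and the
    excised bond partner."""

    hydrogen: Atom
    anchor: Atom
    removed: Atom
    rule: LinkAtomRule | None


@dataclass(eq=False)
class FragmentSpec:
    """A QM region: source atoms (in residue order) followed by link hydrogens."""

    label: FragmentLabel
    qm_atoms: list[Atom]
    link_atoms: list[LinkAtom] = field(default_factory=list)
    source_residues: tuple[int, ...] = ()
    chromophore_residues: tuple[int, ...] = ()
    #: serials of the atoms that constitute the chromophore *unit*; pinned at
    #: build time so the set (hence the centroid) is identical in every
    #: fragment regardless of how bridging atoms are reassigned.
    chromophore_serials: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        ids = [id(a) for a in self.qm_atoms]
        if len(set(ids)) != len(ids):
            raise StructureError(f"{self.label}: an atom appears twice")

    @property
    def source_atoms(self) -> list[Atom]:
        n = len(self.qm_atoms) - len(self.link_atoms)
        return self.qm_atoms[:n]

    @property
    def chromophore_atoms(self) -> list[Atom]:
        if self.chromophore_serials:
            return [a for a in self.source_atoms if a.serial in self.chromophore_serials]
        chrom = set(self.chromophore_residues)
        return [a for a in self.source_atoms if a.residue_index in chrom]

    def source_serials(self) -> set[int]:
        return {a.serial for a in self.source_atoms}

    def removed_serials(self) -> set[int]:
        return {la.removed.serial for la in self.link_atoms}


def place_link_hydrogen(anchor: Atom, removed: Atom, bond_length: float) -> Atom:
    """Hydrogen at ``anchor + bond_length * unit(removed - anchor)``."""
    if bond_length <= 0:
        raise ArgumentError("bond_length must be positive")
    direction = removed.coords - anchor.coords
    norm = float(np.linalg.norm(direction))
    if norm < 1e-8:
        raise GeometryError(
            f"anchor {anchor.name} and removed {removed.name} atoms coincide"
        )
    coords = anchor.coords + bond_length * direction / norm
    return Atom(
        serial=-1,
        name="H",
        element="H",
        coords=coords,
        residue_index=anchor.residue_index,
    )


def unit_atoms(system: MolecularSystem, i: int) -> list[Atom]:
    """Atoms of fragmentation unit ``i`` (bridging O3' reassigned downstream).

    An unlinked residue (the non-covalent chromophore, a lone ligand chain) is
    its own unit verbatim.
    """
    r = system.residue(i)
    atoms = list(r.atoms)
    if system.chain_neighbor(i, +1) is not None:
        atoms = [a for a in atoms if a.name != "O3'"]
    pred = system.chain_neighbor(i, -1)
    if pred is not None:
        atoms.append(_cut_atom(system, pred, "O3'"))
    return atoms


def _cut_atom(system: MolecularSystem, i: int, name: str) -> Atom:
    r = system.residue(i)
    if not r.has_atom(name):
        raise StructureError(
            f"cut-site atom {name!r} missing from residue {i} ({r.name})"
        )
    return r.atom(name)


def sever_and_cap(
    system: MolecularSystem,
    residue_subset: Iterable[int],
    label: FragmentLabel | None = None,
    rules: dict[str, LinkAtomRule] = DEFAULT_LINK_RULES,
) -> FragmentSpec:
    """Build the QM region for ``residue_subset`` and cap every severed
    C3'-O3' bond crossing its boundary."""
    subset = sorted(set(residue_subset))
    if not subset:
        raise ArgumentError("residue subset must be non-empty")
    for i in subset:
        system.residue(i)  # raises ResidueLookupError on unknown indices

    in_subset = set(subset)
    atoms: list[Atom] = []
    for i in subset:
        atoms.extend(unit_atoms(system, i))

    links: list[LinkAtom] = []
    for i in subset:
        pred = system.chain_neighbor(i, -1)
        if pred is not None and pred not in in_subset:
            # upstream bond C3'(pred)-O3'(pred); the fragment keeps O3'(pred)
            rule = rules["O3'"]
            anchor = _cut_atom(system, pred, "O3'")
            removed = _cut_atom(system, pred, "C3'")
            links.append(
                LinkAtom(place_link_hydrogen(anchor, removed, rule.h_bond_length),
                         anchor, removed, rule)
            )
        succ = system.chain_neighbor(i, +1)
        if succ is not None and succ not in in_subset:
            # downstream bond C3'(i)-O3'(i); the fragment keeps C3'(i)
            rule = rules["C3'"]
            anchor = _cut_atom(system, i, "C3'")
            removed = _cut_atom(system, i, "O3'")
            links.append(
                LinkAtom(place_link_hydrogen(anchor, removed, rule.h_bond_length),
                         anchor, removed, rule)
            )

    for k, la in enumerate(links, start=1):
        la.hydrogen.serial = -k
    atoms = atoms + [la.hydrogen for la in links]
    chrom = tuple(i for i in subset if system.residue(i).role == CHROMOPHORE)
    chrom_serials = frozenset(
        a.serial
        for c in chrom
        for a in unit_atoms(system, c)
        if a.residue_index == c
    )
    return FragmentSpec(
        label=label or FragmentLabel("REGION", tuple(subset)),
        qm_atoms=atoms,
        link_atoms=links,
        source_residues=tuple(subset),
        chromophore_residues=chrom,
        chromophore_serials=chrom_serials,
    )


# ---------------------------------------------------------------------------
# Fragment species of the combination formulas
# ---------------------------------------------------------------------------


def _chain_position(system: MolecularSystem, i: int) -> tuple[list[int], int]:
    chain = system.chains[system.residue(i).chain_id]
    return chain, chain.index(i) + 1  # 1-based position within its chain


def build_capped_residue(system: MolecularSystem, i: int) -> FragmentSpec:
    """Residue ``i`` with both whole-residue caps: region {i-1, i, i+1}."""
    pred = system.chain_neighbor(i, -1)
    succ = system.chain_neighbor(i, +1)
    if pred is None or succ is None:
        raise RangeError(
            f"capped residue needs both chain neighbors; residue {i} is terminal"
        )
    return sever_and_cap(
        system, {pred, i, succ}, FragmentLabel("CAPPED_RESIDUE", (i,))
    )


def build_concap(system: MolecularSystem, i: int) -> FragmentSpec:
    """Conjugate cap: the fused neighbor pair {i, i+1}."""
    if system.chain_neighbor(i, -1) is None:
        raise RangeError(f"concap({i}): residue {i} has no 5' predecessor")
    succ = system.chain_neighbor(i, +1)
    if succ is None:
        raise RangeError(f"concap({i}): residue {i} has no 3' successor")
    return sever_and_cap(system, {i, succ}, FragmentLabel("CONCAP", (i,)))


def build_one_body(system: MolecularSystem, m: int) -> FragmentSpec:
    """The chromophore-only (1B) QM region."""
    if system.residue(m).role != CHROMOPHORE:
        raise RoleError(f"residue {m} is not flagged as the chromophore")
    return sever_and_cap(system, {m}, FragmentLabel("ONE_BODY", (m,)))


def build_two_body(system: MolecularSystem, m: int, j: int) -> FragmentSpec:
    """Chromophore plus one H-capped residue: the 2B QM region."""
    if system.residue(m).role != CHROMOPHORE:
        raise RoleError(f"residue {m} is not flagged as the chromophore")
    if j == m:
        raise ArgumentError("two-body partner must differ from the chromophore")
    system.residue(j)
    return sever_and_cap(system, {m, j}, FragmentLabel("TWO_BODY", (m, j)))


def build_ground_pair(system: MolecularSystem, i: int, j: int) -> FragmentSpec:
    """Fused non-neighboring pair for the ground-state two-body term."""
    return sever_and_cap(system, {i, j}, FragmentLabel("PAIR_GROUND", (i, j)))


def build_monomer(system: MolecularSystem, i: int) -> FragmentSpec:
    """Single H-capped unit, the one-body piece of a ground pair term."""
    return sever_and_cap(system, {i}, FragmentLabel("MONOMER", (i,)))


def build_chain_fragment(system: MolecularSystem, chain_id: str) -> FragmentSpec:
    indices = system.chains[chain_id]
    return sever_and_cap(system, indices, FragmentLabel("CHAIN", tuple(indices)))


def build_full_region(system: MolecularSystem) -> FragmentSpec:
    """The whole system as one QM region (the brute-force reference)."""
    return sever_and_cap(
        system, range(1, system.N + 1), FragmentLabel("FULL_SYSTEM")
    )


def build_truncated_full(
    system: MolecularSystem, m: int, lam_fs: float
) -> FragmentSpec:
    """Chromophore plus every residue within ``lam_fs`` (the QM/MM reference
    region)."""
    if lam_fs < 0:
        raise ArgumentError("lambda_FS must be >= 0")
    region = {m, *neighbors_within(system, m, lam_fs)}
    return sever_and_cap(
        system, region, FragmentLabel("TRUNCATED_FULL", (m,), lam_fs)
    )


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairList:
    """Residue pairs selected by a closed distance threshold."""

    pairs: tuple[tuple[int, int], ...]
    threshold: float
    kind: str  # "ground" | "excited"

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def _is_distant(system: MolecularSystem, i: int, j: int) -> bool:
    """True when residues i<j never share a capped fragment: separated by at
    least three positions within one chain, or on different chains."""
    ri, rj = system.residue(i), system.residue(j)
    if ri.chain_id != rj.chain_id:
        return True
    return j >= i + 3


def enumerate_ground_pairs(system: MolecularSystem, lam: float) -> PairList:
    """All distant pairs with closest approach <= lam, ascending (i, j)."""
    if lam < 0:
        raise ArgumentError("lambda must be >= 0")
    pairs = []
    for i in range(1, system.N + 1):
        for j in range(i + 1, system.N + 1):
            if not _is_distant(system, i, j):
                continue
            if lam == math.inf or min_distance(
                system.residue(i).atoms, system.residue(j).atoms
            ) <= lam:
                pairs.append((i, j))
    return PairList(tuple(pairs), lam, "ground")


def enumerate_excited_pairs(
    system: MolecularSystem, m: int, lam_2b: float, bonded: bool = False
) -> PairList:
    """Partners j for the two-body excited-state corrections.

    Nonbonded mode: every residue within ``lam_2b`` of chromophore ``m``.
    Bonded mode: the same minus the local window [m-2, m+2] already covered by
    the capped-fragment terms.
    """
    if lam_2b < 0:
        raise ArgumentError("lambda_2B must be >= 0")
    if not bonded and system.residue(m).role != CHROMOPHORE:
        raise RoleError(f"residue {m} is not flagged as the chromophore")
    chain_id = system.residue(m).chain_id
    js = neighbors_within(system, m, lam_2b)
    if bonded:
        js = [
            j
            for j in js
            if not (system.residue(j).chain_id == chain_id and abs(j - m) <= 2)
        ]
    return PairList(tuple((m, j) for j in js), lam_2b, "excited")


# ---------------------------------------------------------------------------
# Interchange: XYZ geometry + JSON manifest
# ---------------------------------------------------------------------------


def write_xyz(fragment: FragmentSpec, path: str | Path) -> Path:
    path = Path(path)
    lines = [str(len(fragment.qm_atoms)), str(fragment.label)]
    for a in fragment.qm_atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:18.8f} {y:18.8f} {z:18.8f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def fragment_manifest(fragment: FragmentSpec) -> dict:
    return {
        "schema_version": 1,
        "label": str(fragment.label),
        "kind": fragment.label.kind,
        "indices": list(fragment.label.indices),
        "threshold": fragment.label.threshold,
        "source_residues": list(fragment.source_residues),
        "chromophore_residues": list(fragment.chromophore_residues),
        "chromophore_serials": sorted(fragment.chromophore_serials),
        "atoms": [
            {
                "serial": a.serial,
                "name": a.name,
                "element": a.element,
                "residue_index": a.residue_index,
                "is_link": a.serial < 0,
            }
            for a in fragment.qm_atoms
        ],
        "link_atoms": [
            {
                "anchor_serial": la.anchor.serial,
                "anchor_name": la.anchor.name,
                "removed_serial": la.removed.serial,
                "removed_name": la.removed.name,
                "removed_element": la.removed.element,
                "removed_coords": la.removed.coords.tolist(),
                "bond_length": la.rule.h_bond_length if la.rule else None,
            }
            for la in fragment.link_atoms
        ],
    }


def write_fragment(fragment: FragmentSpec, directory: str | Path) -> Path:
    """Serialize a fragment as <slug>.xyz plus a <slug>.json sidecar; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    slug = fragment.label.slug()
    write_xyz(fragment, directory / f"{slug}.xyz")
    manifest = directory / f"{slug}.json"
    manifest.write_text(json.dumps(fragment_manifest(fragment), indent=1))
    return manifest
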
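"""Deterministic toy fluorophore / pseudo-RNA generators and mock presets.

The toy residues are chemically nonsensical minimal templates — six atoms with
the backbone names the fragmenter needs (P, C3', O3') plus a small sidegroup.
Realism is not the goal; geometric and bookkeeping fidelity is: the intra-unit
C3'-O3' ester bond is 1.5 angstrom, chain neighbors abut through an O3'...P
gap of 1.6 angstrom, and the rigid six-atom chromophore is placed so that its
*measured* minimum distance to each requested contact residue equals the
requested value (solved radially per contact, verified to 0.05 angstrom).

Residues not named in ``contact_distances`` are parked on a distant row so the
requested contacts are the only sub-threshold approaches to the chromophore.

The model charges live in one table (:data:`TOY_CHARGES`), keyed by atom name,
shared by the generated :class:`~eegmfcc.embedding.ChargeModel` and by the mock
engine presets, so MM background charges and the mock's internal QM charges
describe the same physics. Cut-site atoms (C3', O3') carry zero charge, which
makes dropping link-replaced background charges energy-neutral: the presets
isolate the combinatorial assembly itself, leaving capping artifacts out of the
oracle identities by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .embedding import ChargeModel, write_charge_table  # re-export  # noqa: F401
from .errors import ArgumentError, ConstructionError
from .qm import DEFAULT_EPSILON, MockEngineParams
from .structure import (
    Atom,
    MolecularSystem,
    Residue,
    min_distance,
    select_chromophore,
    write_pdb,  # re-export  # noqa: F401
)

#: Model charge (e) per atom name; every template below sums to an integer.
TOY_CHARGES = {
    "P": 0.40,
    "C1'": 0.10,
    "N1": -0.30,
    "O2": -0.20,
    "C3'": 0.00,
    "O3'": 0.00,
    "S1": 0.20,
    "C2": 0.10,
    "N3": -0.30,
    "C4": 0.10,
    "C5": 0.10,
    "O6": -0.20,
}

# (name, element, template offset in angstrom)
NUCLEOTIDE_TEMPLATE = [
    ("P", "P", (0.0, 0.0, 0.0)),
    ("C1'", "C", (0.9, 1.3, 0.4)),
    ("N1", "N", (1.9, 2.1, -0.3)),
    ("O2", "O", (2.9, 1.1, 0.6)),
    ("C3'", "C", (2.0, 0.0, 0.0)),
    ("O3'", "O", (3.5, 0.0, 0.0)),
]

CHROMOPHORE_TEMPLATE = [
    ("S1", "S", (0.0, 0.0, 0.0)),
    ("C2", "C", (1.7, 0.2, 0.1)),
    ("N3", "N", (2.4, 1.4, 0.0)),
    ("C4", "C", (1.7, 2.6, 0.1)),
    ("C5", "C", (0.2, 2.5, 0.3)),
    ("O6", "O", (-0.6, 1.3, 0.2)),
]

#: Chromophore grafted covalently into a chain: backbone plus a ring stub.
BONDED_CHROMOPHORE_TEMPLATE = [
    ("P", "P", (0.0, 0.0, 0.0)),
    ("C3'", "C", (2.0, 0.0, 0.0)),
    ("O3'", "O", (3.5, 0.0, 0.0)),
    ("S1", "S", (0.8, 1.4, 0.5)),
    ("C2", "C", (2.2, 2.0, 0.2)),
    ("O6", "O", (3.2, 2.8, 0.8)),
]
# charge sums: nucleotide 0.0; EKJ 0.0; bonded EKB 0.4+0.2+0.1-0.2 = 0.5 -> fix
# by swapping the ring stub charges below.
BONDED_RING_CHARGES = {"S1": 0.20, "C2": 0.10, "O6": -0.70}

NUCLEOTIDE_NAMES = ("A", "G", "C", "U")
SPACING = 5.1  # angstrom between chain origins on a row
JITTER = 0.08  # seeded sidegroup jitter amplitude
FAR_ROW = 12.0  # extra clearance of non-contact residues from the pocket


@dataclass
class ToySpec:
    """Conditions for one synthetic complex."""

    n_residues: int = 5
    contact_distances: dict[int, float] = field(default_factory=dict)
    seed: int = 1
    chromophore_resname: str = "EKJ"
    chain_id: str = "A"
    chromophore_chain: str = "B"


def _residue_atoms(template, origin, serial0, residue_index, jitter_rng=None):
    atoms = []
    for k, (name, element, offset) in enumerate(template):
        off = np.asarray(offset, dtype=float)
        if jitter_rng is not None and name not in ("P", "C3'", "O3'"):
            off = off + jitter_rng.uniform(-JITTER, JITTER, 3)
        atoms.append(
            Atom(
                serial=serial0 + k,
                name=name,
                element=element,
                coords=np.asarray(origin, dtype=float) + off,
                residue_index=residue_index,
            )
        )
    return atoms


def make_chain(
    n_residues: int,
    seed: int = 0,
    origins: list | None = None,
    chain_id: str = "A",
) -> MolecularSystem:
    """A bare pseudo-RNA chain; ``origins`` overrides the straight layout."""
    if n_residues < 1:
        raise ArgumentError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    residues = []
    serial = 1
    for i in range(1, n_residues + 1):
        origin = (
            origins[i - 1]
            if origins is not None
            else np.array([(i - 1) * SPACING, 0.0, 0.0])
        )
        atoms = _residue_atoms(NUCLEOTIDE_TEMPLATE, origin, serial, i, rng)
        serial += len(atoms)
        residues.append(
            Residue(
                index=i,
                name=NUCLEOTIDE_NAMES[(i - 1) % 4],
                chain_id=chain_id,
                atoms=atoms,
            )
        )
    return MolecularSystem(residues=residues)


def toy_charge_model() -> ChargeModel:
    """Template charge model covering every toy residue type."""
    templates: dict[tuple[str, str], float] = {}
    for resname in NUCLEOTIDE_NAMES:
        for name, _el, _off in NUCLEOTIDE_TEMPLATE:
            templates[(resname, name)] = TOY_CHARGES[name]
    for name, _el, _off in CHROMOPHORE_TEMPLATE:
        templates[("EKJ", name)] = TOY_CHARGES[name]
    for name, _el, _off in BONDED_CHROMOPHORE_TEMPLATE:
        templates[("EKB", name)] = BONDED_RING_CHARGES.get(name, TOY_CHARGES[name])
    return ChargeModel(templates=templates, provenance="template")


def _place_radially(chrom_coords, template_coords, direction, target):
    """Distance t along ``direction`` at which min_dist(template+t*u, chrom)
    equals ``target`` (monotone beyond overlap; solved by bracketing)."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)

    def gap(t):
        return min_distance(template_coords + t * u, chrom_coords) - target

    t_hi = target + 20.0
    if gap(0.0) > 0 or gap(t_hi) < 0:
        raise ConstructionError(
            f"cannot reach contact distance {target} along {u}"
        )
    return brentq(gap, 0.0, t_hi, xtol=1e-10)


def make_toy_complex(
    spec: ToySpec | None = None,
    n_residues: int | None = None,
    contact_distances: dict[int, float] | None = None,
    seed: int = 1,
) -> tuple[MolecularSystem, ChargeModel]:
    """Build a pseudo-RNA chain plus a rigid non-covalent chromophore.

    Contact residues are arranged radially around the chromophore at their
    requested minimum distances; the rest of the chain sits on a distant row.
    Deterministic for a fixed spec/seed.
    """
    if spec is None:
        if n_residues is None:
            n_residues = 5
        if contact_distances is None:
            contact_distances = {min(2, n_residues): 3.5}
        spec = ToySpec(
            n_residues=n_residues, contact_distances=dict(contact_distances), seed=seed
        )
    if spec.n_residues < 1:
        raise ArgumentError("n_residues must be >= 1")
    for j, d in spec.contact_distances.items():
        if not 1 <= j <= spec.n_residues:
            raise ArgumentError(f"contact residue {j} outside 1..{spec.n_residues}")
        if d < 1.5:
            raise ArgumentError(f"contact distance {d} < 1.5 angstrom is infeasible")

    rng = np.random.default_rng(spec.seed)
    chrom_offsets = np.array([o for _n, _e, o in CHROMOPHORE_TEMPLATE], dtype=float)
    chrom_center = chrom_offsets.mean(axis=0)
    chrom_coords = chrom_offsets - chrom_center  # chromophore centered at origin

    max_d = max(spec.contact_distances.values(), default=3.5)
    contacts = sorted(spec.contact_distances)
    angles = {
        j: 2 * np.pi * k / max(len(contacts), 1) + rng.uniform(0, 0.3)
        for k, j in enumerate(contacts)
    }

    # jitter sidegroups first, then solve contact placement against the
    # *actual* per-residue offsets so the requested distances are met exactly
    per_residue_offsets = []
    for i in range(1, spec.n_residues + 1):
        offs = []
        for name, _el, off in NUCLEOTIDE_TEMPLATE:
            off = np.asarray(off, dtype=float)
            if name not in ("P", "C3'", "O3'"):
                off = off + rng.uniform(-JITTER, JITTER, 3)
            offs.append(off)
        per_residue_offsets.append(np.array(offs))

    far_y = -(max_d + FAR_ROW)
    residues = []
    serial = 1
    for i in range(1, spec.n_residues + 1):
        offsets = per_residue_offsets[i - 1]
        if i in spec.contact_distances:
            theta = angles[i]
            u = np.array([np.cos(theta), np.sin(theta), 0.15])
            u = u / np.linalg.norm(u)
            t = _place_radially(
                chrom_coords, offsets, u, spec.contact_distances[i]
            )
            origin = t * u
        else:
            origin = np.array([(i - 1) * SPACING, far_y, 0.0])
        atoms = [
            Atom(
                serial=serial + k,
                name=name,
                element=element,
                coords=origin + offsets[k],
                residue_index=i,
            )
            for k, (name, element, _off) in enumerate(NUCLEOTIDE_TEMPLATE)
        ]
        serial += len(atoms)
        residues.append(
            Residue(
                index=i,
                name=NUCLEOTIDE_NAMES[(i - 1) % 4],
                chain_id=spec.chain_id,
                atoms=atoms,
            )
        )

    chrom_atoms = [
        Atom(
            serial=serial + k,
            name=name,
            element=element,
            coords=chrom_coords[k],
            residue_index=spec.n_residues + 1,
        )
        for k, (name, element, _off) in enumerate(CHROMOPHORE_TEMPLATE)
    ]
    residues = residues + [
        Residue(
            index=spec.n_residues + 1,
            name=spec.chromophore_resname,
            chain_id=spec.chromophore_chain,
            atoms=chrom_atoms,
        )
    ]
    system = MolecularSystem(residues=residues)
    select_chromophore(system, spec.chromophore_resname)

    # verify the generator met its own contract
    m = spec.n_residues + 1
    for j, d in spec.contact_distances.items():
        got = min_distance(system.residue(j).atoms, system.residue(m).atoms)
        if abs(got - d) > 0.05:
            raise ConstructionError(
                f"contact residue {j}: requested {d} angstrom, achieved {got:.3f}"
            )
    for j in range(1, spec.n_residues + 1):
        if j in spec.contact_distances:
            continue
        if min_distance(system.residue(j).atoms, system.residue(m).atoms) < max_d + 2:
            raise ConstructionError(
                f"non-contact residue {j} intrudes into the binding pocket"
            )
    return system, toy_charge_model()


def make_bonded_toy(
    n_residues: int = 7, m: int | None = None, seed: int = 3
) -> tuple[MolecularSystem, ChargeModel, int]:
    """A straight chain with the chromophore grafted covalently at position
    ``m`` (default: middle). Returns (system, charges, m)."""
    if n_residues < 5:
        raise ArgumentError("bonded toy needs at least 5 residues")
    m = m or (n_residues + 1) // 2
    if not 3 <= m <= n_residues - 2:
        raise ArgumentError("chromophore must sit at least two residues from ends")
    rng = np.random.default_rng(seed)
    residues = []
    serial = 1
    for i in range(1, n_residues + 1):
        origin = np.array([(i - 1) * SPACING, 0.0, 0.0])
        if i == m:
            atoms = _residue_atoms(
                BONDED_CHROMOPHORE_TEMPLATE, origin, serial, i, None
            )
            name = "EKB"
        else:
            atoms = _residue_atoms(NUCLEOTIDE_TEMPLATE, origin, serial, i, rng)
            name = NUCLEOTIDE_NAMES[(i - 1) % 4]
        serial += len(atoms)
        residues.append(Residue(index=i, name=name, chain_id="A", atoms=atoms))
    system = MolecularSystem(residues=residues)
    select_chromophore(system, "EKB")
    return system, toy_charge_model(), m


def standard_toy(seed: int = 1) -> tuple[MolecularSystem, ChargeModel, int]:
    """The 8-residue benchmark complex used by the oracle suites: contacts at
    2.8, 3.6 and 4.5 angstrom so the two-body neighborhood grows with the
    threshold. Returns (system, charges, chromophore index)."""
    system, model = make_toy_complex(
        n_residues=8, contact_distances={2: 2.8, 4: 3.6, 6: 4.5}, seed=seed
    )
    return system, model, 9


# ---------------------------------------------------------------------------
# Mock-engine presets
# ---------------------------------------------------------------------------


def _base_params(rng: np.random.Generator) -> dict:
    return dict(
        omega0=3.0 + rng.uniform(-0.2, 0.4),
        alpha=0.7 + 0.2 * rng.uniform(),
        beta=0.4 + 0.2 * rng.uniform(),
        gamma=0.4 + 0.2 * rng.uniform(),
        mu0=np.array([2.0, 0.5, 0.2]) + rng.uniform(-0.1, 0.1, 3),
        epsilon=dict(DEFAULT_EPSILON),
        atom_charges=dict(TOY_CHARGES),
    )


def preset_pairwise(seed: int = 1) -> MockEngineParams:
    """Strictly pairwise mock: two-body assembly over all contacts reproduces
    the full-system values exactly (the central oracle)."""
    rng = np.random.default_rng(seed)
    return MockEngineParams(delta=0.0, **_base_params(rng))


def preset_nonadditive(seed: int = 1) -> MockEngineParams:
    """Adds a positive non-pairwise excitation term so the two-body assembly
    error is nonzero and shrinks monotonically as the threshold grows.

    The QM-environment and background couplings are tied (alpha == beta) so the
    residual is the non-pairwise term alone — each admitted residue then
    strictly removes a positive share of the error, which is what makes the
    convergence monotone by construction.
    """
    rng = np.random.default_rng(seed)
    params = _base_params(rng)
    params["beta"] = params["alpha"]
    return MockEngineParams(delta=0.05 + 0.03 * rng.uniform(), **params)
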
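"""Engine-agnostic per-fragment QM contract plus a deterministic mock engine.

A real electronic-structure program plugs in through the file interchange
(:func:`serialize_task` / :func:`parse_result`); the mock engine implements the
same contract with closed-form energies so every assembly formula can be tested
against an exactly computable full-system reference.

Mock model
----------
Each atom carries a fixed internal charge ``q̂`` (by atom name; link hydrogens
carry zero). With ``d_p`` the distance of atom/charge ``p`` from the
chromophore centroid:

* ground energy   ``E = Σ_F ε(element) + Σ_{a<b∈F} q̂q̂/r + Σ_{a∈F,b∈B} q̂q/r``
  (hartree, r in bohr) — a genuine pairwise embedded energy, so the
  fragment-assembly identities can be checked exactly;
* excitation      ``ω = ω₀ + α Σ_env q̂/d + β Σ_bg q/d + δ (Σ_env |q̂|/d)²`` (eV,
  d in angstrom); ``env`` is the QM region minus the chromophore. δ adds a
  controlled non-pairwise term (zero in the pairwise regime);
* TEDM            ``μ = μ₀ + γ Σ_env q̂ (r−r_c)/d²`` (a.u.);
* forces          analytic gradient of ``E' = E + ω/27.211...`` with respect to
  the chromophore atom positions (hartree/bohr).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .constants import BOHR_PER_ANGSTROM, HARTREE_EV
from .embedding import ChargeSet, read_charges, write_charges
from .errors import (
    ArgumentError,
    CapabilityError,
    EngineError,
    EEGMFCCError,
    RoleError,
    SchemaError,
    SingularityError,
    ValidationError,
)
from .fragmentation import (
    FragmentLabel,
    FragmentSpec,
    LinkAtom,
    fragment_manifest,
    write_xyz,
)
from .structure import Atom

ALL_PROPERTIES = frozenset({"ground_energy", "excitation", "tedm", "forces"})

#: Mock per-element self-energies (hartree); loosely atom-like magnitudes.
DEFAULT_EPSILON = {"H": -0.5, "C": -3.8, "N": -5.4, "O": -7.5, "P": -34.1, "S": -39.8}


@dataclass(eq=False)
class QMTask:
    fragment: FragmentSpec
    background: ChargeSet = field(default_factory=ChargeSet)
    method_tag: str = "mock"
    state_index: int = 1
    wants: frozenset[str] = ALL_PROPERTIES

    def __post_init__(self) -> None:
        self.wants = frozenset(self.wants)
        if self.state_index < 1:
            raise ArgumentError("state_index must be >= 1")
        if not self.fragment.qm_atoms:
            raise ArgumentError("fragment has no atoms")
        unknown = self.wants - ALL_PROPERTIES
        if unknown:
            raise ArgumentError(f"unknown properties requested: {sorted(unknown)}")


@dataclass(eq=False)
class QMResult:
    """Per-fragment result. ``e_ground`` is the embedded total energy (self +
    interaction with background charges), ``e_excited`` its excited-state
    counterpart, ``omega_ev`` their gap in eV."""

    e_ground: float | None = None
    e_excited: float | None = None
    omega_ev: float | None = None
    tedm: np.ndarray | None = None
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tedm is not None:
            self.tedm = np.asarray(self.tedm, dtype=float).reshape(3)
            if not np.all(np.isfinite(self.tedm)):
                raise ValidationError("non-finite TEDM")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(self.forces)):
                raise ValidationError("non-finite forces")
        if self.e_ground is not None and self.e_excited is not None:
            implied = (self.e_excited - self.e_ground) * HARTREE_EV
            if self.omega_ev is None:
                self.omega_ev = implied
            elif abs(implied - self.omega_ev) > 1e-6:
                raise ValidationError(
                    f"omega {self.omega_ev} eV contradicts energies "
                    f"(implied {implied} eV)"
                )

    @classmethod
    def from_energies(cls, e_ground: float, e_excited: float, **kw) -> "QMResult":
        return cls(
            e_ground=e_ground,
            e_excited=e_excited,
            omega_ev=(e_excited - e_ground) * HARTREE_EV,
            **kw,
        )


def run(task: QMTask, engine) -> QMResult:
    """Execute a task on an engine, enforcing the capability contract."""
    missing = task.wants - getattr(engine, "capabilities", ALL_PROPERTIES)
    if missing:
        raise CapabilityError(
            f"engine {engine!r} does not provide {sorted(missing)}"
        )
    try:
        return engine.run(task)
    except EEGMFCCError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise EngineError(f"{task.fragment.label}: {exc}") from exc


# ---------------------------------------------------------------------------
# Mock engine
# ---------------------------------------------------------------------------


@dataclass
class MockEngineParams:
    """Closed-form mock coefficients.

    alpha couples the chromophore to QM-treated environment atoms, beta to
    background charges (alpha != beta models the QM-vs-MM treatment
    difference); delta turns on a non-pairwise excitation term.
    """

    omega0: float = 3.1  # eV
    alpha: float = 0.8  # eV * angstrom / e
    beta: float = 0.8  # eV * angstrom / e
    gamma: float = 0.5  # a.u. * angstrom / e (TEDM response)
    delta: float = 0.0  # eV * (angstrom/e)^2, non-pairwise channel
    mu0: np.ndarray = field(default_factory=lambda: np.array([2.0, 0.5, 0.2]))
    epsilon: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPSILON))
    atom_charges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(3)
        vals = [self.omega0, self.alpha, self.beta, self.gamma, self.delta]
        if not all(map(math.isfinite, vals)):
            raise ArgumentError("mock parameters must be finite")


class MockEngine:
    """Deterministic closed-form engine (see module docstring)."""

    capabilities = ALL_PROPERTIES

    def __init__(self, params: MockEngineParams | None = None) -> None:
        self.params = params or MockEngineParams()

    # internal fixed charge model ------------------------------------------------
    def model_charge(self, atom: Atom) -> float:
        if atom.serial < 0:  # link hydrogen: inert
            return 0.0
        return self.params.atom_charges.get(atom.name, 0.0)

    def run(self, task: QMTask) -> QMResult:
        p = self.params
        frag = task.fragment
        atoms = frag.qm_atoms
        coords = np.array([a.coords for a in atoms])
        qhat = np.array([self.model_charge(a) for a in atoms])
        bg = task.background
        bq = bg.q() if len(bg) else np.zeros(0)
        bxyz = bg.coords() if len(bg) else np.zeros((0, 3))

        e_ground = self._ground(atoms, coords, qhat, bq, bxyz)

        needs_excited = task.wants & {"excitation", "tedm", "forces"}
        omega = tedm = forces = None
        if needs_excited:
            chrom = frag.chromophore_atoms
            if not chrom:
                raise RoleError(
                    f"{frag.label}: excited-state properties need a chromophore "
                    "in the QM region"
                )
            chrom_ids = {id(a) for a in chrom}
            env_mask = np.array([id(a) not in chrom_ids for a in atoms])
            centroid = np.mean([a.coords for a in chrom], axis=0)
            omega = self._omega(coords, qhat, env_mask, centroid, bq, bxyz)
            tedm = self._tedm(coords, qhat, env_mask, centroid)
            if "forces" in task.wants:
                forces = self._forces(
                    atoms, coords, qhat, env_mask, chrom, centroid, bq, bxyz
                )

        result = QMResult(
            e_ground=e_ground if ("ground_energy" in task.wants or needs_excited) else None,
            e_excited=(e_ground + omega / HARTREE_EV) if omega is not None else None,
            omega_ev=omega if "excitation" in task.wants or omega is not None else None,
            tedm=tedm if "tedm" in task.wants else None,
            forces=forces,
        )
        return result

    # pieces ---------------------------------------------------------------------
    def _ground(self, atoms, coords, qhat, bq, bxyz) -> float:
        eps = math.fsum(self.params.epsilon.get(a.element, 0.0) for a in atoms)
        terms = [eps]
        charged = np.nonzero(qhat)[0]
        if len(charged) > 1:
            u = coords[charged] * BOHR_PER_ANGSTROM
            q = qhat[charged]
            diff = u[:, None, :] - u[None, :, :]
            r = np.linalg.norm(diff, axis=-1)
            iu = np.triu_indices(len(q), k=1)
            if np.any(r[iu] < 1e-10):
                raise SingularityError("coincident QM atoms in mock Coulomb sum")
            terms.append(float(np.sum(np.outer(q, q)[iu] / r[iu])))
        if len(charged) and len(bq):
            u = coords[charged] * BOHR_PER_ANGSTROM
            v = bxyz * BOHR_PER_ANGSTROM
            r = np.linalg.norm(u[:, None, :] - v[None, :, :], axis=-1)
            if np.any(r < 1e-10):
                raise SingularityError("background charge coincides with QM atom")
            terms.append(float(np.sum(np.outer(qhat[charged], bq) / r)))
        return math.fsum(terms)

    def _env_dists(self, coords, env_mask, centroid):
        d = np.linalg.norm(coords[env_mask] - centroid, axis=-1)
        if np.any(d < 1e-8):
            raise SingularityError("environment atom at the chromophore centroid")
        return d

    def _omega(self, coords, qhat, env_mask, centroid, bq, bxyz) -> float:
        p = self.params
        omega = p.omega0
        qe = qhat[env_mask]
        if len(qe):
            d = self._env_dists(coords, env_mask, centroid)
            omega += p.alpha * math.fsum(qe / d)
            if p.delta:
                omega += p.delta * math.fsum(np.abs(qe) / d) ** 2
        if len(bq):
            db = np.linalg.norm(bxyz - centroid, axis=-1)
            if np.any(db < 1e-8):
                raise SingularityError("background charge at the chromophore centroid")
            omega += p.beta * math.fsum(bq / db)
        return omega

    def _tedm(self, coords, qhat, env_mask, centroid) -> np.ndarray:
        p = self.params
        mu = p.mu0.copy()
        qe = qhat[env_mask]
        if len(qe):
            d = self._env_dists(coords, env_mask, centroid)
            rel = coords[env_mask] - centroid
            mu = mu + p.gamma * np.sum(qe[:, None] * rel / d[:, None] ** 2, axis=0)
        return mu

    def _forces(self, atoms, coords, qhat, env_mask, chrom, centroid, bq, bxyz):
        """-dE'/dr over chromophore atoms, hartree/bohr, analytic."""
        p = self.params
        n_c = len(chrom)
        chrom_ids = [i for i, a in enumerate(atoms) if id(a) in {id(c) for c in chrom}]
        grads = np.zeros((n_c, 3))

        # ground Coulomb part (bohr coordinates)
        u = coords * BOHR_PER_ANGSTROM
        ub = bxyz * BOHR_PER_ANGSTROM
        for out_i, k in enumerate(chrom_ids):
            if qhat[k] == 0.0:
                continue
            for x in range(len(atoms)):
                if x == k or qhat[x] == 0.0:
                    continue
                dvec = u[k] - u[x]
                r = np.linalg.norm(dvec)
                grads[out_i] += -qhat[k] * qhat[x] * dvec / r**3
            for b in range(len(bq)):
                dvec = u[k] - ub[b]
                r = np.linalg.norm(dvec)
                grads[out_i] += -qhat[k] * bq[b] * dvec / r**3

        # omega part: d(1/d_p)/dr_k = (r_p - r_c) / (n_C d_p^3), per component
        def centroid_grad(points, weights):
            d = np.linalg.norm(points - centroid, axis=-1)
            rel = points - centroid
            return np.sum(weights[:, None] * rel / d[:, None] ** 3, axis=0) / n_c

        grad_omega = np.zeros(3)  # eV / angstrom, identical for every chromophore atom
        qe = qhat[env_mask]
        if len(qe):
            pe = coords[env_mask]
            grad_omega += p.alpha * centroid_grad(pe, qe)
            if p.delta:
                d = self._env_dists(coords, env_mask, centroid)
                t = math.fsum(np.abs(qe) / d)
                grad_omega += p.delta * 2.0 * t * centroid_grad(pe, np.abs(qe))
        if len(bq):
            grad_omega += p.beta * centroid_grad(bxyz, bq)
        grads += grad_omega / (HARTREE_EV * BOHR_PER_ANGSTROM)

        return -grads


# ---------------------------------------------------------------------------
# File interchange
# ---------------------------------------------------------------------------


def serialize_task(task: QMTask, directory: str | Path) -> Path:
    """Write geometry.xyz, charges.txt ("x y z q") and task.json; returns the
    manifest path. Round-trips through :func:`parse_task`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_xyz(task.fragment, directory / "geometry.xyz")
    write_charges(task.background, directory / "charges.txt")
    manifest = {
        "schema_version": 1,
        "method_tag": task.method_tag,
        "state_index": task.state_index,
        "wants": sorted(task.wants),
        "fragment": fragment_manifest(task.fragment),
    }
    path = directory / "task.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def parse_task(directory: str | Path) -> QMTask:
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "task.json").read_text())
        frag_info = manifest["fragment"]
        xyz_lines = (directory / "geometry.xyz").read_text().splitlines()
        n = int(xyz_lines[0])
        coords = [
            [float(v) for v in line.split()[1:4]] for line in xyz_lines[2 : 2 + n]
        ]
    except (KeyError, ValueError, IndexError) as exc:
        raise SchemaError(f"{directory}: malformed task files: {exc}") from exc
    if len(coords) != n or n != len(frag_info["atoms"]):
        raise SchemaError(f"{directory}: geometry/manifest atom count mismatch")

    atoms = [
        Atom(
            serial=rec["serial"],
            name=rec["name"],
            element=rec["element"],
            coords=np.array(xyz),
            residue_index=rec["residue_index"],
        )
        for rec, xyz in zip(frag_info["atoms"], coords)
    ]
    by_serial = {a.serial: a for a in atoms}
    links = []
    link_hs = [a for a in atoms if a.serial < 0]
    for rec, h in zip(frag_info["link_atoms"], link_hs):
        removed = Atom(
            serial=rec["removed_serial"],
            name=rec["removed_name"],
            element=rec.get("removed_element", "X"),
            coords=np.array(rec["removed_coords"]),
        )
        links.append(
            LinkAtom(
                hydrogen=h,
                anchor=by_serial[rec["anchor_serial"]],
                removed=removed,
                rule=None,  # rule length recoverable from rec["bond_length"]
            )
        )
    fragment = FragmentSpec(
        label=FragmentLabel(
            frag_info["kind"],
            tuple(frag_info["indices"]),
            frag_info.get("threshold"),
        ),
        qm_atoms=atoms,
        link_atoms=links,
        source_residues=tuple(frag_info["source_residues"]),
        chromophore_residues=tuple(frag_info["chromophore_residues"]),
        chromophore_serials=frozenset(frag_info.get("chromophore_serials", ())),
    )
    background = read_charges(directory / "charges.txt")
    return QMTask(
        fragment=fragment,
        background=background,
        method_tag=manifest["method_tag"],
        state_index=manifest["state_index"],
        wants=frozenset(manifest["wants"]),
    )


def write_result(result: QMResult, path: str | Path) -> Path:
    payload = {
        "schema_version": 1,
        "e_ground": result.e_ground,
        "e_excited": result.e_excited,
        "omega_ev": result.omega_ev,
        "tedm": None if result.tedm is None else result.tedm.tolist(),
        "forces": None if result.forces is None else result.forces.tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def parse_result(path: str | Path) -> QMResult:
    """Read and validate a result JSON; omega/energy consistency is enforced
    (1e-6 eV) whenever all three fields are present."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: result must be a JSON object")
    known = {"schema_version", "e_ground", "e_excited", "omega_ev", "tedm", "forces"}
    extra = set(payload) - known
    if extra:
        raise SchemaError(f"{path}: unknown fields {sorted(extra)}")
    try:
        return QMResult(
            e_ground=payload.get("e_ground"),
            e_excited=payload.get("e_excited"),
            omega_ev=payload.get("omega_ev"),
            tedm=payload.get("tedm"),
            forces=payload.get("forces"),
        )
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed result fields: {exc}") from exc
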
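"""End-to-end pipelines: fragment a system, run an engine over the fragment
jobs (with or without the embedding field), and assemble the combination
formulas. The CLI is a thin wrapper around these functions.
"""

from __future__ import annotations

import math

from . import assembly
from .embedding import ChargeModel, ChargeSet, background_charges, double_counting_correction
from .fragmentation import (
    FragmentSpec,
    PairList,
    build_capped_residue,
    build_concap,
    build_full_region,
    build_ground_pair,
    build_monomer,
    build_one_body,
    build_truncated_full,
    build_two_body,
    enumerate_excited_pairs,
    enumerate_ground_pairs,
    sever_and_cap,
)
from .qm import QMResult, QMTask, run
from .structure import MolecularSystem

EXCITED_WANTS = frozenset({"ground_energy", "excitation", "tedm", "forces"})


def run_fragment(
    system: MolecularSystem,
    fragment: FragmentSpec,
    model: ChargeModel,
    engine,
    embedded: bool = True,
    wants: frozenset[str] = EXCITED_WANTS,
    method_tag: str = "mock",
    state_index: int = 1,
) -> QMResult:
    """One per-fragment calculation, in the field of the rest of the system
    (``embedded=True``) or in vacuum."""
    background = (
        background_charges(system, fragment, model) if embedded else ChargeSet()
    )
    task = QMTask(
        fragment=fragment,
        background=background,
        method_tag=method_tag,
        state_index=state_index,
        wants=wants,
    )
    return run(task, engine)


def excited_state_report(
    system: MolecularSystem,
    m: int,
    model: ChargeModel,
    engine,
    lambda_2b: float,
    embedded: bool = True,
    bonded: bool = False,
    wants: frozenset[str] = EXCITED_WANTS,
    method_tag: str = "mock",
    state_index: int = 1,
) -> assembly.AssemblyReport:
    """Assembled excitation energy, TEDM, oscillator strength and chromophore
    forces at two-body threshold ``lambda_2b``."""

    def _run(frag, frag_wants=wants):
        return run_fragment(
            system, frag, model, engine,
            embedded=embedded, wants=frag_wants,
            method_tag=method_tag, state_index=state_index,
        )

    res_m = _run(build_one_body(system, m))
    pairs = enumerate_excited_pairs(system, m, lambda_2b, bonded=bonded)
    pair_results: dict[int, QMResult] = {
        j: _run(build_two_body(system, m, j)) for _m, j in pairs
    }

    pair_omegas = {j: r.omega_ev for j, r in pair_results.items()}
    if bonded:
        capped = {
            i: _run(build_capped_residue(system, i), frozenset({"excitation"})).omega_ev
            for i in (m - 1, m, m + 1)
        }
        concaps = {
            i: _run(build_concap(system, i), frozenset({"excitation"})).omega_ev
            for i in (m - 1, m)
        }
        local = math.fsum(capped.values()) - math.fsum(concaps.values())
        omega = assembly.excitation_energy_bonded(
            capped, concaps, pair_omegas, res_m.omega_ev
        )
        report = assembly.AssemblyReport(
            omega_1b=local,
            pair_corrections={j: w - res_m.omega_ev for j, w in pair_omegas.items()},
            lambda_2b=lambda_2b,
            embedding=embedded,
            bonded=True,
        )
        assert abs(report.omega_assembled - omega) < 1e-9
    else:
        omega, report = assembly.excitation_energy_nonbonded(
            res_m.omega_ev, pair_omegas
        )
        report.lambda_2b = lambda_2b
        report.embedding = embedded

    if "tedm" in wants:
        report.tedm_assembled = assembly.assemble_tedm(
            res_m.tedm, {j: r.tedm for j, r in pair_results.items()}
        )
        report.oscillator_strength = assembly.oscillator_strength(
            report.omega_assembled, report.tedm_assembled
        )
    if "forces" in wants:
        report.forces_assembled = assembly.assemble_forces(
            res_m.forces, {j: r.forces for j, r in pair_results.items()}
        )
    return report


def _linked_runs(system: MolecularSystem, indices: list[int]) -> list[list[int]]:
    """Split a chain's residue indices into maximal backbone-linked runs."""
    runs: list[list[int]] = []
    current = [indices[0]]
    for prev, nxt in zip(indices, indices[1:]):
        if system.chain_neighbor(prev, +1) == nxt:
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    runs.append(current)
    return runs


def ground_state_energy(
    system: MolecularSystem,
    model: ChargeModel,
    engine,
    lambda_pairs: float,
    method_tag: str = "mock",
) -> float:
    """Total ground-state energy (hartree) from embedded capped-residue,
    concap and distant-pair fragment calculations.

    The MM double-counting term covers the distant pairs *not* promoted to QM
    treatment: every distant pair enters the embedded one-body sums twice at
    MM level, and the QM pair correction already replaces both copies for the
    treated pairs.
    """

    def _run(frag):
        return run_fragment(
            system, frag, model, engine,
            embedded=True, wants=frozenset({"ground_energy"}),
            method_tag=method_tag,
        ).e_ground

    capped: dict[str, float] = {}
    concaps: dict[str, float] = {}
    for chain_indices in system.chains.values():
        for seg in _linked_runs(system, chain_indices):
            if len(seg) <= 2:
                frag = sever_and_cap(system, seg)
                capped[str(frag.label)] = _run(frag)
                continue
            for i in seg[1:-1]:
                frag = build_capped_residue(system, i)
                capped[str(frag.label)] = _run(frag)
            for i in seg[1:-2]:
                frag = build_concap(system, i)
                concaps[str(frag.label)] = _run(frag)

    qm_pairs = enumerate_ground_pairs(system, lambda_pairs)
    mono_cache: dict[int, float] = {}

    def _mono(i: int) -> float:
        if i not in mono_cache:
            mono_cache[i] = _run(build_monomer(system, i))
        return mono_cache[i]

    pair_terms = {
        (i, j): (_run(build_ground_pair(system, i, j)), _mono(i), _mono(j))
        for i, j in qm_pairs
    }

    all_pairs = enumerate_ground_pairs(system, math.inf)
    treated = set(qm_pairs.pairs)
    untreated = PairList(
        tuple(p for p in all_pairs if p not in treated), math.inf, "ground"
    )
    e_dc = double_counting_correction(system, untreated, model)

    return assembly.ground_state_energy(capped, concaps, pair_terms, e_dc)


def full_system_reference(
    system: MolecularSystem,
    model: ChargeModel,
    engine,
    wants: frozenset[str] = EXCITED_WANTS,
) -> QMResult:
    """Brute-force reference: the whole system as one QM region, no background."""
    return run_fragment(
        system, build_full_region(system), model, engine, embedded=False, wants=wants
    )


def truncated_reference(
    system: MolecularSystem,
    m: int,
    model: ChargeModel,
    engine,
    lambda_fs: float,
    wants: frozenset[str] = EXCITED_WANTS,
) -> QMResult:
    """QM/MM reference: chromophore plus all residues within ``lambda_fs`` as
    the QM region, the rest as background charges."""
    frag = build_truncated_full(system, m, lambda_fs)
    return run_fragment(system, frag, model, engine, embedded=True, wants=wants)


def decomposition_table(
    system: MolecularSystem,
    m: int,
    model: ChargeModel,
    engine,
    lambda_2b: float,
    method_tag: str = "mock",
):
    """Embedding-free per-residue spectral-shift decomposition."""
    wants = frozenset({"excitation"})
    res_m = run_fragment(
        system, build_one_body(system, m), model, engine,
        embedded=False, wants=wants, method_tag=method_tag,
    )
    pairs = enumerate_excited_pairs(system, m, lambda_2b)
    pair_omegas = {}
    names = {}
    for _m, j in pairs:
        r = run_fragment(
            system, build_two_body(system, m, j), model, engine,
            embedded=False, wants=wants, method_tag=method_tag,
        )
        pair_omegas[j] = r.omega_ev
        names[j] = f"{system.residue(j).name}{j}"
    return assembly.decompose_per_residue(
        res_m.omega_ev, pair_omegas, embedded=False, names=names
    )


def benchmark_point(
    system: MolecularSystem,
    m: int,
    model: ChargeModel,
    engine,
    lambda_2b: float,
    lambda_fs: float,
) -> tuple[float, float, float]:
    """(omega_1B, omega_2B, omega_reference) for one system — the raw material
    of a deviation table."""
    wants = frozenset({"excitation"})
    one = excited_state_report(
        system, m, model, engine, lambda_2b=0.0, wants=wants
    ).omega_assembled
    two = excited_state_report(
        system, m, model, engine, lambda_2b=lambda_2b, wants=wants
    ).omega_assembled
    ref = truncated_reference(system, m, model, engine, lambda_fs, wants).omega_ev
    return one, two, ref
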
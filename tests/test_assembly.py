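"""Combination-formula arithmetic: excitation, TEDM, f, forces, decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegmfcc.assembly import (
    assemble_forces,
    assemble_tedm,
    decompose_per_residue,
    excitation_energy_bonded,
    excitation_energy_nonbonded,
    ground_state_energy,
    oscillator_strength,
    snapshot_average,
)
from eegmfcc.errors import (
    AlignmentError,
    ArgumentError,
    CompletenessError,
    ProvenanceError,
)


class TestGroundStateArithmetic:
    def test_three_residue_chain_collapses(self):
        # one capped fragment covering the whole chain, nothing else
        e = ground_state_energy({2: -42.5}, {}, {}, 0.0)
        assert e == pytest.approx(-42.5, abs=1e-15)

    def test_term_isolation_without_pairs(self):
        capped = {2: -10.0, 3: -11.0, 4: -12.0}
        concaps = {2: -5.0, 3: -6.0}
        e = ground_state_energy(capped, concaps, {}, 0.0)
        assert e == pytest.approx(-33.0 + 11.0, abs=1e-12)

    def test_pair_terms_and_double_counting(self):
        pairs = {(1, 4): (-20.0, -9.0, -10.5)}
        e = ground_state_energy({2: -30.0}, {}, pairs, e_dc=0.25)
        assert e == pytest.approx(-30.0 + (-20.0 + 9.0 + 10.5) - 0.25, abs=1e-12)

    def test_missing_fragment_results(self):
        with pytest.raises(CompletenessError, match="CAP"):
            ground_state_energy(
                {2: -10.0}, {}, {}, 0.0, expected_capped=["CAP(2)", "CAP(3)"]
            )


class TestExcitationAssembly:
    def test_no_neighbors_is_one_body(self):
        omega, report = excitation_energy_nonbonded(3.309, {})
        assert omega == 3.309
        assert report.pair_corrections == {}

    def test_single_pair_collapse(self):
        # a single two-body partner: the assembled energy is the pair energy
        omega, report = excitation_energy_nonbonded(3.309, {13: 3.499})
        assert omega == pytest.approx(3.499, abs=1e-12)
        assert report.pair_corrections[13] == pytest.approx(0.190, abs=1e-12)

    def test_report_invariant(self):
        _omega, report = excitation_energy_nonbonded(
            3.0, {1: 3.1, 2: 2.95, 3: 3.002}
        )
        assert report.omega_assembled == pytest.approx(
            report.omega_1b + math.fsum(report.pair_corrections.values()), abs=1e-12
        )

    @given(st.lists(st.floats(2.0, 4.0), min_size=2, max_size=8))
    def test_order_invariance(self, omegas):
        pair = {j: w for j, w in enumerate(omegas, start=1)}
        shuffled = dict(reversed(list(pair.items())))
        w1, _ = excitation_energy_nonbonded(3.0, pair)
        w2, _ = excitation_energy_nonbonded(3.0, shuffled)
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_telescoping_neighbor_changes_nothing(self):
        base, _ = excitation_energy_nonbonded(3.1, {2: 3.25})
        extended, _ = excitation_energy_nonbonded(3.1, {2: 3.25, 7: 3.1})
        assert extended == pytest.approx(base, abs=1e-15)


class TestBondedExcitation:
    def test_perfectly_localized_telescopes(self):
        # neighbors' capped fragments share one omega, concaps match it: the
        # local combination collapses onto the central fragment's omega
        omega = excitation_energy_bonded(
            {3: 3.0, 4: 3.4, 5: 3.0}, {3: 3.0, 4: 3.0}, {}, omega_m=3.4
        )
        assert omega == pytest.approx(3.4, abs=1e-12)

    def test_far_pairs_add_corrections(self):
        omega = excitation_energy_bonded(
            {3: 3.0, 4: 3.4, 5: 3.0}, {3: 3.0, 4: 3.0}, {9: 3.45}, omega_m=3.4
        )
        assert omega == pytest.approx(3.45, abs=1e-12)

    def test_incomplete_local_fragments(self):
        with pytest.raises(CompletenessError):
            excitation_energy_bonded({3: 3.0}, {3: 3.0, 4: 3.0}, {}, 3.4)


class TestTEDMAndOscillator:
    def test_no_neighbors_keeps_one_body_tedm(self):
        mu = assemble_tedm([3.2193, 1.0487, 0.7567], {})
        np.testing.assert_allclose(mu, [3.2193, 1.0487, 0.7567], atol=1e-15)

    def test_zero_corrections(self):
        mu_m = np.array([1.0, 2.0, 3.0])
        mu = assemble_tedm(mu_m, {1: mu_m.copy(), 2: mu_m.copy()})
        np.testing.assert_allclose(mu, mu_m, atol=1e-15)

    def test_oscillator_strength_reference_rows(self):
        assert oscillator_strength(3.0019, [2.7694, 0.9656, 0.6412]) == pytest.approx(
            0.6629, abs=5e-4
        )
        assert oscillator_strength(2.9954, [2.9222, 1.0278, 0.6810]) == pytest.approx(
            0.7382, abs=5e-4
        )

    def test_zero_dipole(self):
        assert oscillator_strength(3.0, [0.0, 0.0, 0.0]) == 0.0

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ArgumentError):
            oscillator_strength(0.0, [1.0, 0, 0])

    @given(
        st.floats(0.1, 10.0),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    )
    def test_nonnegative_for_all_inputs(self, omega, mu):
        assert oscillator_strength(omega, mu) >= 0.0


class TestForces:
    def test_no_neighbors(self):
        f = np.array([[1.0, 0, 0], [0, -1.0, 0]])
        np.testing.assert_allclose(assemble_forces(f, {}), f)

    def test_zero_correction_neighbor(self):
        f = np.arange(12.0).reshape(4, 3)
        out = assemble_forces(f, {5: f.copy()})
        np.testing.assert_allclose(out, f, atol=1e-15)

    def test_misaligned_arrays(self):
        f = np.zeros((4, 3))
        with pytest.raises(AlignmentError):
            assemble_forces(f, {1: np.zeros((3, 3))})
        with pytest.raises(AlignmentError):
            assemble_forces(np.zeros(3), {})


class TestDecomposition:
    def test_reference_shifts(self):
        table = decompose_per_residue(
            3.309, {12: 3.261, 13: 3.499, 17: 3.399},
            names={12: "A12", 13: "G13", 17: "A17"},
        )
        by = table.set_index("residue")
        assert by.loc["A12", "dEx_meV"] == pytest.approx(-48.0, abs=1e-9)
        assert by.loc["G13", "dEx_meV"] == pytest.approx(190.0, abs=1e-9)
        assert by.loc["A17", "dEx_meV"] == pytest.approx(90.0, abs=1e-9)
        assert by.loc["A12", "shift_direction"] == "red"
        assert by.loc["G13", "shift_direction"] == "blue"
        # red shift = longer wavelength
        assert by.loc["A12", "dWL_nm"] > 0 > by.loc["G13", "dWL_nm"]
        assert by.loc["G13", "dWL_nm"] == pytest.approx(-20.4, abs=0.2)

    def test_identical_pair_gives_zero(self):
        table = decompose_per_residue(3.309, {5: 3.309})
        row = table.iloc[0]
        assert row["dEx_meV"] == 0.0
        assert row["dWL_nm"] == 0.0
        assert row["shift_direction"] == "none"

    def test_embedded_inputs_refused(self):
        with pytest.raises(ProvenanceError):
            decompose_per_residue(3.309, {12: 3.261}, embedded=True)


class TestSnapshotAverage:
    def test_single_snapshot_identity(self):
        t = decompose_per_residue(3.3, {1: 3.35, 2: 3.28})
        out = snapshot_average([t])
        np.testing.assert_allclose(out["dEx_meV"], t["dEx_meV"], atol=1e-12)
        assert (out["n_snapshots"] == 1).all()

    def test_two_snapshot_mean(self):
        t1 = decompose_per_residue(3.3, {1: 3.310})
        t2 = decompose_per_residue(3.3, {1: 3.320})
        out = snapshot_average([t1, t2])
        assert out.loc[0, "dEx_meV"] == pytest.approx(15.0, abs=1e-9)

    def test_missing_residues_averaged_where_present(self):
        t1 = decompose_per_residue(3.3, {1: 3.31, 2: 3.32})
        t2 = decompose_per_residue(3.3, {1: 3.33})
        out = snapshot_average([t1, t2]).set_index("residue")
        assert out.loc[1, "n_snapshots"] == 2
        assert out.loc[2, "n_snapshots"] == 1
        assert out.loc[2, "dEx_meV"] == pytest.approx(20.0, abs=1e-9)

    def test_matches_manual_summation(self, rng):
        tables = [
            decompose_per_residue(
                3.3, {j: 3.3 + rng.uniform(-0.1, 0.1) for j in range(1, 5)}
            )
            for _ in range(6)
        ]
        out = snapshot_average(tables).set_index("residue")
        for j in range(1, 5):
            manual = np.mean([t.set_index("residue").loc[j, "dEx_meV"] for t in tables])
            assert out.loc[j, "dEx_meV"] == pytest.approx(manual, rel=1e-12)

    def test_empty_input(self):
        with pytest.raises(ArgumentError):
            snapshot_average([])
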
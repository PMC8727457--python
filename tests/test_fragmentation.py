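"""Severing, capping and fragment enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegmfcc import fixtures
from eegmfcc.errors import (
    GeometryError,
    RangeError,
    ResidueLookupError,
    RoleError,
)
from eegmfcc.fragmentation import (
    build_capped_residue,
    build_concap,
    build_one_body,
    build_truncated_full,
    build_two_body,
    enumerate_excited_pairs,
    enumerate_ground_pairs,
    place_link_hydrogen,
    sever_and_cap,
    write_fragment,
)
from eegmfcc.structure import Atom, min_distance


def _expected_cuts(system, subset):
    """Brute-force count of backbone bonds crossing the subset boundary."""
    cuts = 0
    for i in subset:
        pred = system.chain_neighbor(i, -1)
        succ = system.chain_neighbor(i, +1)
        cuts += pred is not None and pred not in subset
        cuts += succ is not None and succ not in subset
    return cuts


class TestPlaceLinkHydrogen:
    def test_collinear_placements(self):
        a = Atom(1, "C3'", "C", np.zeros(3))
        r = Atom(2, "O3'", "O", np.array([0.0, 0, 1.6]))
        h = place_link_hydrogen(a, r, 1.09)
        np.testing.assert_allclose(h.coords, [0, 0, 1.09], atol=1e-12)

        a2 = Atom(1, "O3'", "O", np.array([1.0, 1, 1]))
        r2 = Atom(2, "C3'", "C", np.array([1.0, 1, 2.6]))
        h2 = place_link_hydrogen(a2, r2, 0.96)
        np.testing.assert_allclose(h2.coords, [1, 1, 1.96], atol=1e-12)

    @given(
        st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        st.floats(0.5, 2.0),
    )
    def test_length_and_collinearity(self, coords, length):
        anchor = np.array(coords[:3])
        removed = np.array(coords[3:])
        if np.linalg.norm(removed - anchor) < 1e-3:
            removed = anchor + np.array([1.0, 0, 0])
        h = place_link_hydrogen(
            Atom(1, "A", "C", anchor), Atom(2, "R", "O", removed), length
        )
        assert np.linalg.norm(h.coords - anchor) == pytest.approx(length, abs=1e-12)
        cross = np.cross(h.coords - anchor, removed - anchor)
        assert np.linalg.norm(cross) == pytest.approx(0, abs=1e-9)
        assert np.dot(h.coords - anchor, removed - anchor) > 0  # on the bond ray

    def test_coincident_atoms_rejected(self):
        a = Atom(1, "A", "C", np.zeros(3))
        with pytest.raises(GeometryError):
            place_link_hydrogen(a, Atom(2, "R", "O", np.zeros(3)), 1.0)


class TestSeverAndCap:
    def test_interior_residue_two_caps(self):
        system = fixtures.make_chain(5, seed=0)
        frag = sever_and_cap(system, {3})
        assert len(frag.link_atoms) == 2
        # unit bookkeeping: the swap of own O3' for the inherited one is
        # count-neutral, so totals match the residue plus its caps
        assert len(frag.qm_atoms) == len(system.residue(3).atoms) + 2
        lengths = sorted(
            round(np.linalg.norm(la.hydrogen.coords - la.anchor.coords), 9)
            for la in frag.link_atoms
        )
        assert lengths == [0.96, 1.09]

    def test_whole_chain_no_caps(self):
        system = fixtures.make_chain(5, seed=0)
        frag = sever_and_cap(system, range(1, 6))
        assert frag.link_atoms == []
        assert len(frag.qm_atoms) == system.atom_count

    def test_noncovalent_chromophore_untouched(self, toy_complex):
        system, _ = toy_complex
        frag = sever_and_cap(system, {6})
        assert frag.link_atoms == []
        assert [a.serial for a in frag.qm_atoms] == [
            a.serial for a in system.residue(6).atoms
        ]

    def test_unknown_residue(self, toy_complex):
        system, _ = toy_complex
        with pytest.raises(ResidueLookupError):
            sever_and_cap(system, {42})

    @pytest.mark.parametrize("subset", [
        {1}, {5}, {2, 3}, {1, 4}, {2, 4}, {1, 2, 5}, {1, 2, 3, 4, 5},
    ])
    def test_link_count_matches_boundary_bonds(self, subset):
        system = fixtures.make_chain(5, seed=2)
        frag = sever_and_cap(system, subset)
        assert len(frag.link_atoms) == _expected_cuts(system, subset)
        system_serials = {a.serial for a in system.atoms()}
        assert frag.source_serials() <= system_serials

    def test_link_geometry_exact_across_random_fragments(self, rng):
        """Every cap sits at exactly its rule length, over 100 random subsets."""
        system = fixtures.make_chain(9, seed=4)
        checked = 0
        for _ in range(100):
            k = int(rng.integers(1, 5))
            subset = set(rng.choice(np.arange(1, 10), size=k, replace=False).tolist())
            frag = sever_and_cap(system, subset)
            for la in frag.link_atoms:
                d = np.linalg.norm(la.hydrogen.coords - la.anchor.coords)
                assert abs(d - la.rule.h_bond_length) < 1e-9
                direction = la.removed.coords - la.anchor.coords
                cosang = np.dot(la.hydrogen.coords - la.anchor.coords, direction) / (
                    d * np.linalg.norm(direction)
                )
                assert cosang == pytest.approx(1.0, abs=1e-12)
                checked += 1
        assert checked > 100


class TestBuilders:
    def test_capped_residue_interior(self):
        system = fixtures.make_chain(5, seed=0)
        frag = build_capped_residue(system, 3)
        assert frag.source_residues == (2, 3, 4)
        assert len(frag.link_atoms) == 2

    def test_capped_residue_near_terminus_single_cap(self):
        system = fixtures.make_chain(5, seed=0)
        frag = build_capped_residue(system, 2)
        assert frag.source_residues == (1, 2, 3)
        assert len(frag.link_atoms) == 1  # no 5' bond beyond residue 1

    def test_capped_residue_terminal_is_range_error(self):
        system = fixtures.make_chain(5, seed=0)
        for i in (1, 5):
            with pytest.raises(RangeError):
                build_capped_residue(system, i)

    def test_capped_conservation_over_interior(self):
        # unit bookkeeping: a fragment inherits the bridging O3' from upstream
        # (+1 unless the run starts the chain) and cedes its own to downstream
        # (-1 unless the run ends the chain); links account for the rest
        system = fixtures.make_chain(7, seed=1)
        for i in range(2, 7):
            frag = build_capped_residue(system, i)
            member_atoms = sum(len(system.residue(j).atoms) for j in frag.source_residues)
            lo, hi = min(frag.source_residues), max(frag.source_residues)
            delta = (1 if lo > 1 else 0) - (1 if hi < 7 else 0)
            assert len(frag.qm_atoms) == member_atoms + len(frag.link_atoms) + delta

    def test_concap_pairs_and_range(self):
        system = fixtures.make_chain(5, seed=0)
        built = [build_concap(system, i) for i in (2, 3, 4)]
        assert [f.source_residues for f in built] == [(2, 3), (3, 4), (4, 5)]
        with pytest.raises(RangeError):
            build_concap(system, 1)
        with pytest.raises(RangeError):
            build_concap(system, 5)

        three = fixtures.make_chain(3, seed=0)
        assert build_concap(three, 2).source_residues == (2, 3)
        for i in (1, 3):
            with pytest.raises(RangeError):
                build_concap(three, i)

    def test_two_body_is_disjoint_union(self, toy_complex):
        system, _ = toy_complex
        frag = build_two_body(system, 6, 2)
        one = build_one_body(system, 6)
        capped_j = sever_and_cap(system, {2})
        assert frag.source_serials() == one.source_serials() | capped_j.source_serials()
        assert not (one.source_serials() & capped_j.source_serials())
        assert len(frag.link_atoms) == 2  # interior nucleotide: both bonds cut

    def test_two_body_terminal_partner_one_cap(self, toy_complex):
        system, _ = toy_complex
        assert len(build_two_body(system, 6, 1).link_atoms) == 1
        assert len(build_two_body(system, 6, 5).link_atoms) == 1

    def test_two_body_requires_chromophore(self, toy_complex):
        system, _ = toy_complex
        with pytest.raises(RoleError):
            build_two_body(system, 3, 2)

    def test_truncated_full_regions(self, toy_complex):
        system, _ = toy_complex
        assert build_truncated_full(system, 6, 0.0).source_residues == (6,)
        assert build_truncated_full(system, 6, 4.0).source_residues == (2, 6)
        r4 = set(build_truncated_full(system, 6, 4.0).source_residues)
        r7 = set(build_truncated_full(system, 6, 7.0).source_residues)
        assert r4 <= r7


class TestPairEnumeration:
    def test_straight_chain_no_contacts(self):
        system = fixtures.make_chain(6, seed=0)
        assert enumerate_ground_pairs(system, 2.0).pairs == ()

    def test_combinatorial_enumeration_at_infinity(self):
        system = fixtures.make_chain(6, seed=0)
        pairs = enumerate_ground_pairs(system, math.inf).pairs
        assert pairs == ((1, 4), (1, 5), (1, 6), (2, 5), (2, 6), (3, 6))

    def test_hairpin_matches_brute_force(self):
        origins = [np.array([(i - 1) * 5.1, 0.0, 0.0]) for i in range(1, 6)]
        origins[4] = np.array([0.0, 6.0, 0.0])  # fold residue 5 back over 1
        system = fixtures.make_chain(5, seed=3, origins=origins)
        lam = 4.0
        expected = tuple(
            (i, j)
            for i in range(1, 6)
            for j in range(i + 3, 6)
            if min_distance(system.residue(i).atoms, system.residue(j).atoms) <= lam
        )
        got = enumerate_ground_pairs(system, lam).pairs
        assert got == expected
        assert (1, 5) in got  # the engineered fold-back contact

    def test_cross_chain_pairs_always_distant(self, toy_complex):
        system, _ = toy_complex
        pairs = enumerate_ground_pairs(system, math.inf).pairs
        assert {(i, 6) for i in range(1, 6)} <= set(pairs)

    def test_excited_pairs_threshold_and_monotone(self, toy_complex):
        system, _ = toy_complex
        assert enumerate_excited_pairs(system, 6, 4.0).pairs == ((6, 2),)
        p4 = set(enumerate_excited_pairs(system, 6, 4.0).pairs)
        p5 = set(enumerate_excited_pairs(system, 6, 6.5).pairs)
        assert p4 <= p5

    def test_excited_pairs_role_check(self, toy_complex):
        system, _ = toy_complex
        with pytest.raises(RoleError):
            enumerate_excited_pairs(system, 3, 4.0)

    def test_bonded_mode_excludes_local_window(self):
        system, _model, m = fixtures.make_bonded_toy(n_residues=7, seed=3)
        pairs = enumerate_excited_pairs(system, m, math.inf, bonded=True)
        js = {j for _m, j in pairs}
        assert js == {1, 7}  # everything in [m-2, m+2] telescopes locally

    def test_bonded_mode_all_local_is_empty(self):
        system, _model, m = fixtures.make_bonded_toy(n_residues=5, seed=3)
        assert enumerate_excited_pairs(system, m, math.inf, bonded=True).pairs == ()


class TestInterchange:
    def test_write_fragment_files(self, toy_complex, tmp_path):
        system, _ = toy_complex
        frag = build_two_body(system, 6, 2)
        manifest_path = write_fragment(frag, tmp_path)
        xyz = manifest_path.with_suffix(".xyz")
        assert xyz.exists()
        lines = xyz.read_text().splitlines()
        assert int(lines[0]) == len(frag.qm_atoms)
        import json

        manifest = json.loads(manifest_path.read_text())
        assert manifest["source_residues"] == [2, 6]
        assert manifest["chromophore_residues"] == [6]
        assert len(manifest["link_atoms"]) == 2
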
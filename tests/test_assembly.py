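"""Kabsch superposition, rigid-body assembly, clash detection, mass ledger."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ogdhc import synthetic_data as sd
from ogdhc.assembly import (
    AssembledModel,
    LedgerEntry,
    Transform,
    assemble_complex,
    composition_mass,
    detect_clashes,
    kabsch_superpose,
)
from ogdhc.structure_io import Structure


def random_points(rng, n):
    return rng.uniform(-20, 20, size=(n, 3))


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2]])
        tf, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0, atol=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(0)
        mobile = random_points(rng, 10)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        reference = mobile @ rot.T + np.array([1.0, 1.0, 1.0])
        tf, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, rot, atol=1e-9)
        assert np.allclose(tf.translation, [1, 1, 1], atol=1e-9)

    def test_matches_planar_grid_search_oracle(self):
        """3-point asymmetric planar case vs exhaustive in-plane rotation grid
        at 0.1° (plus the plane-reversing branch), optimal translation by
        centroid alignment for each angle."""
        mobile = np.array([[0.0, 0, 0], [2, 0, 0], [0.5, 1.3, 0]])
        reference = np.array([[0.0, 0, 0], [1, 0, 0], [0.4, 0.9, 0]])
        _, rmsd = kabsch_superpose(mobile, reference)

        mu_m = mobile.mean(axis=0)
        mu_r = reference.mean(axis=0)
        x = mobile - mu_m
        y = reference - mu_r
        best = np.inf
        flip = np.diag([1.0, -1.0, -1.0])  # proper rotation reversing the plane
        for deg in np.arange(0.0, 360.0, 0.1):
            rot = Rotation.from_euler("z", deg, degrees=True).as_matrix()
            for r in (rot, rot @ flip):
                d = x @ r.T - y
                best = min(best, float(np.sqrt(np.mean(np.sum(d**2, axis=1)))))
        assert rmsd == pytest.approx(best, abs=1e-4)
        assert rmsd <= best + 1e-12  # closed form cannot be beaten by the grid

    def test_reflection_is_not_returned(self):
        """Mirrored target: best proper rotation leaves a residual, and the
        returned rotation still has det +1."""
        rng = np.random.default_rng(3)
        mobile = random_points(rng, 8)
        reference = mobile * np.array([1.0, 1.0, -1.0])  # improper image
        tf, rmsd = kabsch_superpose(mobile, reference)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    @pytest.mark.parametrize("seed", range(4))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = random_points(rng, 12)
        b = a + rng.normal(0, 1.0, size=a.shape)
        _, rmsd0 = kabsch_superpose(a, b)
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        _, rmsd1 = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, rel=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy_align_vectors(self, seed):
        """Independent cross-check: scipy's weighted-vector alignment solves
        the same least-squares problem after centering."""
        rng = np.random.default_rng(seed)
        mobile = random_points(rng, 10)
        reference = mobile @ Rotation.random(random_state=seed).as_matrix().T
        reference += rng.normal(0, 0.5, size=mobile.shape) + rng.uniform(-30, 30, 3)
        tf, rmsd = kabsch_superpose(mobile, reference)
        rot_scipy, rssd = Rotation.align_vectors(
            reference - reference.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        assert np.allclose(tf.rotation, rot_scipy.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(mobile)), rel=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="shape"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_improper_transform_rejected(self):
        with pytest.raises(ValueError, match="proper|orthonormal"):
            Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestAssembly:
    def test_empty_recipe_returns_core(self, mini_complex):
        model = assemble_complex(mini_complex.core, [], [])
        assert model.structure.component_counts() == {"E2o": 24}
        assert model.placements == []

    def test_default_recipe_stoichiometry(self, assembled_mini):
        assert assembled_mini.structure.component_counts() == {
            "E2o": 24, "E1o": 16, "E3": 12, "MRPS36": 6,
        }
        assembled_mini.validate()

    def test_placement_rmsd_near_zero_by_construction(self, assembled_mini):
        assert max(p.rmsd for p in assembled_mini.placements) < 1e-6

    def test_assembled_coordinates_match_ground_truth(self, mini_complex, assembled_mini):
        """Placed chains land on the reference built directly in the core frame."""
        ref = mini_complex.assembled_reference
        got = assembled_mini.structure
        assert len(ref.chains) == len(got.chains)
        for cr, cg in zip(ref.chains, got.chains):
            assert cr.component == cg.component
            a = np.array([at.position for r in cr.residues for at in r.atoms])
            b = np.array([at.position for r in cg.residues for at in r.atoms])
            assert np.abs(a - b).max() < 1e-6

    def test_atom_count_conservation(self, mini_complex, assembled_mini):
        expected = mini_complex.core.n_atoms
        for sm_index, anchor_id, _ in mini_complex.recipe:
            sm = mini_complex.submodels[sm_index]
            expected += sm.n_atoms - sm.chain(anchor_id).n_atoms
        assert assembled_mini.structure.n_atoms == expected

    def test_single_dimer_placement(self, mini_complex):
        model = assemble_complex(
            mini_complex.core, mini_complex.submodels, mini_complex.recipe[:1]
        )
        assert len(model.structure.chains) == 26  # 24 core + 2 new E1o
        assert model.placements[0].rmsd < 1e-6

    def test_duplicate_target_chain_rejected(self, mini_complex):
        recipe = [mini_complex.recipe[0], mini_complex.recipe[0]]
        with pytest.raises(ValueError, match="already used"):
            assemble_complex(mini_complex.core, mini_complex.submodels, recipe)

    def test_too_few_common_residues_rejected(self, mini_complex, point_chain_factory):
        anchor = point_chain_factory(
            "A", "E2o", [(0, 0, 0), (1, 0, 0)], start_number=500
        )
        sub = Structure(chains=[anchor])
        target_id = mini_complex.core.chains[0].id
        with pytest.raises(ValueError, match="share only 0"):
            assemble_complex(mini_complex.core, [sub], [(0, "A", target_id)])

    def test_component_mismatch_rejected(self, mini_complex):
        sub = mini_complex.submodels[0]
        # anchor chain "B" is E1o, target is an E2o core chain
        target_id = mini_complex.recipe[0][2]
        with pytest.raises(ValueError, match="component"):
            assemble_complex(mini_complex.core, [sub], [(0, "B", target_id)])

    def test_ledger_inconsistency_detected(self, assembled_mini):
        broken = AssembledModel(
            structure=assembled_mini.structure,
            ledger=[LedgerEntry("E2o", 99, 41.0)],
            placements=assembled_mini.placements,
            rigid_bodies=assembled_mini.rigid_bodies,
        )
        with pytest.raises(ValueError, match="ledger"):
            broken.validate()


def brute_force_clashes(model, cutoff, exclude=()):
    """O(n²) oracle over all heavy-atom pairs from different rigid bodies."""

    def is_excluded(chain_id, resnum):
        return any(c == chain_id and lo <= resnum <= hi for c, lo, hi in exclude)

    atoms = []
    for ch in model.structure.chains:
        body = model.rigid_bodies.get(ch.id, "core")
        for r in ch.residues:
            for a in r.atoms:
                if a.element.upper() != "H":
                    atoms.append((ch.id, r.number, a.name, np.asarray(a.position), body))
    found = set()
    n_excluded = 0
    for (ca, ra, na, pa, ba), (cb, rb, nb, pb, bb) in itertools.combinations(atoms, 2):
        if ba == bb:
            continue
        if float(np.linalg.norm(pa - pb)) >= cutoff:
            continue
        if is_excluded(ca, ra) or is_excluded(cb, rb):
            n_excluded += 1
            continue
        found.add(frozenset([(ca, ra, na), (cb, rb, nb)]))
    return found, n_excluded


class TestClashes:
    def _two_body_model(self, point_chain_factory, positions_a, positions_b):
        a = point_chain_factory("A", "x", positions_a)
        b = point_chain_factory("B", "y", positions_b)
        return AssembledModel(
            structure=Structure(chains=[a, b]),
            ledger=[LedgerEntry("x", 1, None), LedgerEntry("y", 1, None)],
            placements=[],
            rigid_bodies={"A": "core", "B": "p0"},
        )

    def test_single_close_contact(self, point_chain_factory):
        model = self._two_body_model(point_chain_factory, [(0, 0, 0)], [(1.0, 0, 0)])
        report = detect_clashes(model, cutoff=2.0)
        assert len(report.clashes) == 1
        assert report.clashes[0].distance == pytest.approx(1.0)

    def test_excluded_range_skipped_and_counted(self, point_chain_factory):
        model = self._two_body_model(point_chain_factory, [(0, 0, 0)], [(1.0, 0, 0)])
        report = detect_clashes(model, cutoff=2.0, exclude=[("B", 1, 1)])
        assert report.clashes == []
        assert report.n_excluded == 1

    def test_intra_body_contacts_ignored(self, point_chain_factory):
        model = self._two_body_model(
            point_chain_factory, [(0, 0, 0), (0.5, 0, 0)], [(100.0, 0, 0)]
        )
        assert detect_clashes(model, cutoff=2.0).clashes == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_on_random_fixture(self, seed, point_chain_factory):
        rng = np.random.default_rng(seed)
        pos_a = rng.uniform(0, 30, size=(250, 3))
        pos_b = rng.uniform(0, 30, size=(250, 3))
        model = self._two_body_model(point_chain_factory, pos_a, pos_b)
        exclude = [("A", 1, 40)]
        report = detect_clashes(model, cutoff=2.0, exclude=exclude)
        oracle_pairs, oracle_excluded = brute_force_clashes(model, 2.0, exclude)
        got = {
            frozenset([(c.chain_a, c.residue_a, c.atom_a), (c.chain_b, c.residue_b, c.atom_b)])
            for c in report.clashes
        }
        assert got == oracle_pairs
        assert report.n_excluded == oracle_excluded

    def test_single_body_rejected(self, point_chain_factory):
        a = point_chain_factory("A", "x", [(0, 0, 0)])
        model = AssembledModel(Structure(chains=[a]), [], [], {"A": "core"})
        with pytest.raises(ValueError, match="two rigid"):
            detect_clashes(model)


class TestCompositionMass:
    def test_default_stoichiometry_mass(self):
        ledger = [
            LedgerEntry("E1o", 16, 111.0),
            LedgerEntry("E2o", 24, 41.0),
            LedgerEntry("E3", 12, 50.0),
            LedgerEntry("MRPS36", 6, 11.0),
        ]
        kda, mda = composition_mass(ledger)
        assert kda == pytest.approx(3426.0)
        assert mda == pytest.approx(3.426)

    def test_empty_ledger_zero(self):
        assert composition_mass([]) == (0.0, 0.0)

    def test_simple_product(self):
        assert composition_mass([LedgerEntry("x", 2, 50.0)])[0] == pytest.approx(100.0)

    def test_missing_mass_names_component(self):
        with pytest.raises(ValueError, match="MRPS36"):
            composition_mass([LedgerEntry("MRPS36", 6, None)])

    def test_override_table_takes_precedence(self, assembled_mini):
        kda, _ = composition_mass(assembled_mini, monomer_masses_kda=sd.MONOMER_MASSES_KDA)
        assert kda == pytest.approx(3426.0)
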
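"""Cutoff scanning, environment extraction and signature assembly."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from csmpred.errors import UnsupportedResidueError, WildTypeMismatchError
from csmpred.signature import (
    SignatureParams,
    assemble_signature,
    compute_signature,
    cutoff_scan,
    extract_residue_environment,
    geometric_centre,
    pair_class_labels,
    pairwise_distances,
    pharmacophore_change,
    signature_length,
)
from csmpred.structure import (
    PHARMACOPHORE_CLASSES,
    THREE_TO_ONE,
    AtomRecord,
    ProteinStructure,
)

from oracles import (
    all_pairs_auc,  # noqa: F401  (used in test_learning)
    brute_force_scan,
    naive_distance_matrix,
    tally_residue,
)


def _atom(name, coords, cls="hydrophobic", res=("A", 1, "GLY")):
    chain, num, resname = res
    return AtomRecord(
        serial=1, atom_name=name, element=name[0], residue_name=resname,
        residue_number=num, chain_id=chain, coords=np.array(coords, float),
        pharmacophore=cls,
    )


class TestGeometry:
    def test_centre_single_atom_identity(self):
        assert geometric_centre([_atom("C1", (1, 2, 3))]) == pytest.approx([1, 2, 3])

    def test_centre_midpoint(self):
        atoms = [_atom("C1", (0, 0, 0)), _atom("C2", (2, 0, 0))]
        assert geometric_centre(atoms) == pytest.approx([1, 0, 0])

    def test_centre_translation_equivariance(self, rng):
        coords = rng.normal(size=(7, 3))
        t = np.array([3.0, -1.0, 2.5])
        atoms = [_atom(f"C{i}", c) for i, c in enumerate(coords)]
        moved = [_atom(f"C{i}", c + t) for i, c in enumerate(coords)]
        assert geometric_centre(moved) == pytest.approx(geometric_centre(atoms) + t)

    def test_centre_empty_raises(self):
        with pytest.raises(ValueError):
            geometric_centre([])

    def test_pairwise_345_triangle(self):
        atoms = [_atom("A", (0, 0, 0)), _atom("B", (3, 0, 0)), _atom("C", (3, 4, 0))]
        d = pairwise_distances(atoms)
        assert d[0, 1] == pytest.approx(3)
        assert d[1, 2] == pytest.approx(4)
        assert d[0, 2] == pytest.approx(5)

    def test_pairwise_symmetric_zero_diagonal(self, rng):
        atoms = [_atom(f"C{i}", c) for i, c in enumerate(rng.normal(size=(20, 3)) * 5)]
        d = pairwise_distances(atoms)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_pairwise_matches_naive_double_loop(self, rng):
        coords = rng.uniform(-10, 10, size=(50, 3))
        atoms = [_atom(f"C{i}", c) for i, c in enumerate(coords)]
        expected = np.array(naive_distance_matrix(coords))
        assert np.allclose(pairwise_distances(atoms), expected, atol=1e-9)

    def test_single_atom_environment_matrix(self):
        assert pairwise_distances([_atom("C1", (0, 0, 0))]).shape == (1, 1)


class TestEnvironment:
    def _structure_with_probes(self):
        atoms = [
            _atom("N", (0, 0.5, 0), "hydrogen_donor"),
            _atom("CA", (0, -0.5, 0), "hydrophobic"),
            _atom("C1", (9.9, 0, 0), res=("A", 2, "GLY")),
            _atom("C2", (10.1, 0, 0), res=("A", 3, "GLY")),
        ]
        return ProteinStructure("probe", atoms)

    def test_boundary_is_inclusive(self):
        structure = self._structure_with_probes()
        env = extract_residue_environment(structure, ("A", 1), radius=10.0)
        names = {a.atom_name for a in env.atoms}
        assert "C1" in names and "C2" not in names

    def test_saturation_at_large_radius(self, cloud_structure):
        env = extract_residue_environment(cloud_structure, cloud_structure.residues()[0], 1e4)
        assert len(env.atoms) == len(cloud_structure.atoms)

    def test_membership_matches_brute_force(self, rng):
        coords = rng.uniform(0, 30, size=(200, 3))
        atoms = [_atom("CA", coords[0], res=("A", 1, "GLY"))]
        atoms += [
            _atom(f"C{i}", c, res=("B", i + 2, "GLY")) for i, c in enumerate(coords[1:])
        ]
        structure = ProteinStructure("rand", atoms)
        env = extract_residue_environment(structure, ("A", 1), radius=10.0)
        centre = coords[0]
        expected = {
            a.atom_name
            for a in atoms
            if np.sqrt(((a.coords - centre) ** 2).sum()) <= 10.0 + 1e-9
        }
        assert {a.atom_name for a in env.atoms} == expected

    def test_own_atoms_always_included(self, cloud_structure):
        key = cloud_structure.residues()[3]
        env = extract_residue_environment(cloud_structure, key, radius=2.5)
        own = {id(a) for a in cloud_structure.residue_atoms(key)}
        present = {a.atom_name for a in env.atoms if a.residue_key == key}
        assert len(present) >= 1
        assert all(any(a.residue_key == key for a in env.atoms) for _ in own)


class TestCutoffScan:
    def test_step_function_two_atoms(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        params = SignatureParams(d_min=2, d_max=6, d_step=2)
        scan = cutoff_scan(d, ["hydrophobic", "hydrophobic"], params, "one_class")
        assert scan.counts[:, 0].tolist() == [0, 1, 1]

    def test_pair_class_bookkeeping(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = SignatureParams(d_min=0, d_max=4, d_step=1)
        scan = cutoff_scan(
            d, ["hydrophobic", "hydrogen_acceptor"], params, "pharmacophore"
        )
        col = scan.pair_labels.index("hydrophobic|hydrogen_acceptor")
        for c, row in zip(scan.cutoffs, scan.counts):
            assert row.sum() == (1 if c >= 1 else 0)
            assert row[col] == (1 if c >= 1 else 0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_triple_loop(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 60))
        coords = rng.uniform(0, 12, size=(n, 3))
        classes = [str(rng.choice(PHARMACOPHORE_CLASSES)) for _ in range(n)]
        d = np.array(naive_distance_matrix(coords))
        params = SignatureParams()
        for scheme in ("one_class", "binary", "pharmacophore"):
            scan = cutoff_scan(d, classes, params, scheme)
            expected = brute_force_scan(coords, classes, params.cutoffs, scheme)
            for lab, col in zip(scan.pair_labels, scan.counts.T):
                assert col.tolist() == expected[lab], (scheme, lab)

    def test_columns_cumulative_and_saturate(self, rng):
        coords = rng.uniform(0, 8, size=(30, 3))
        classes = [str(rng.choice(PHARMACOPHORE_CLASSES)) for _ in range(30)]
        d = np.array(naive_distance_matrix(coords))
        params = SignatureParams(d_max=20.0)  # beyond max pairwise distance
        scan = cutoff_scan(d, classes, params, "one_class")
        assert (np.diff(scan.counts, axis=0) >= 0).all()
        assert scan.counts[-1, 0] == 30 * 29 // 2

    def test_scheme_consistency_sums(self, rng):
        coords = rng.uniform(0, 10, size=(40, 3))
        classes = [str(rng.choice(PHARMACOPHORE_CLASSES)) for _ in range(40)]
        d = np.array(naive_distance_matrix(coords))
        params = SignatureParams()
        one = cutoff_scan(d, classes, params, "one_class")
        binary = cutoff_scan(d, classes, params, "binary")
        pharma = cutoff_scan(d, classes, params, "pharmacophore")
        assert (binary.counts.sum(axis=1) == one.counts[:, 0]).all()
        assert (pharma.counts.sum(axis=1) == one.counts[:, 0]).all()

    def test_label_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cutoff_scan(np.zeros((3, 3)), ["hydrophobic"] * 2, SignatureParams(), "one_class")


class TestPharmacophoreChange:
    def test_identity_mutation_zero(self, table):
        assert pharmacophore_change("A", "A", table).tolist() == [0] * 8

    def test_antisymmetry(self, table):
        fwd = pharmacophore_change("G", "W", table)
        assert (pharmacophore_change("W", "G", table) == -fwd).all()

    def test_gly_to_trp_matches_independent_tally(self, table):
        change = pharmacophore_change("G", "W", table)
        trp, gly = tally_residue(table, "W"), tally_residue(table, "G")
        expected = [trp[c] - gly[c] for c in PHARMACOPHORE_CLASSES]
        assert change.tolist() == expected

    def test_nonstandard_code_raises(self, table):
        with pytest.raises(UnsupportedResidueError):
            pharmacophore_change("X", "G", table)


class TestAssembly:
    def test_default_layout_length_851(self):
        params = SignatureParams()
        assert len(params.cutoffs) == 21
        assert signature_length(params) == 21 * (1 + 3 + 36) + 8 + 3 == 851

    def test_dropping_binary_scheme_shrinks_by_63(self):
        params = SignatureParams(schemes=("one_class", "pharmacophore"))
        assert signature_length(params) == 851 - 21 * 3

    def test_identity_p_change_slots_zero(self, cloud_structure, table):
        key = next(
            k for k in cloud_structure.residues()
            if cloud_structure.residue_name(k) in THREE_TO_ONE
        )
        wt = THREE_TO_ONE[cloud_structure.residue_name(key)]
        sig = compute_signature(
            cloud_structure, key[0], key[1], wt,
            "W" if wt != "W" else "G", table=table, rsa=0.5,
        )
        p_slots = [i for i, n in enumerate(sig.feature_names) if n.startswith("p_change:")]
        assert len(p_slots) == 8
        assert p_slots == list(range(21 * 40, 21 * 40 + 8))

    def test_missing_conditions_imputed_and_flagged(self):
        params = SignatureParams(schemes=("one_class",))
        d = np.zeros((1, 1))
        scan = cutoff_scan(d, ["hydrophobic"], params, "one_class")
        sig = assemble_signature([scan], np.zeros(8), ph=None, temperature=None, rsa=0.3)
        assert sig.provenance["ph_imputed"] and sig.provenance["temperature_imputed"]
        named = sig.as_dict()
        assert named["ph"] == 7.0 and named["temperature"] == 25.0 and named["rsa"] == 0.3

    def test_inconsistent_grids_raise(self):
        a = cutoff_scan(np.zeros((1, 1)), ["hydrophobic"], SignatureParams(), "one_class")
        b = cutoff_scan(
            np.zeros((1, 1)), ["hydrophobic"], SignatureParams(d_step=1.0), "one_class"
        )
        with pytest.raises(ValueError):
            assemble_signature([a, b], np.zeros(8), rsa=0.0)


class TestEndToEnd:
    def _a_site(self, structure):
        key = next(
            k for k in structure.residues() if structure.residue_name(k) in THREE_TO_ONE
        )
        wt = THREE_TO_ONE[structure.residue_name(key)]
        mt = "W" if wt != "W" else "G"
        return key, wt, mt

    def test_deterministic(self, cloud_structure, table):
        key, wt, mt = self._a_site(cloud_structure)
        kwargs = dict(table=table, ph=7.4, temperature=25.0, rsa=0.4)
        one = compute_signature(cloud_structure, key[0], key[1], wt, mt, **kwargs)
        two = compute_signature(cloud_structure, key[0], key[1], wt, mt, **kwargs)
        assert (one.features == two.features).all()

    def test_rigid_motion_invariance(self, cloud_structure, table):
        key, wt, mt = self._a_site(cloud_structure)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -2.0]).as_matrix()
        shift = np.array([11.0, -4.0, 8.0])
        moved = ProteinStructure(
            "moved",
            [replace(a, coords=rot @ a.coords + shift) for a in cloud_structure.atoms],
        )
        kwargs = dict(table=table, ph=7.0, temperature=20.0, rsa=0.4)
        sig_a = compute_signature(cloud_structure, key[0], key[1], wt, mt, **kwargs)
        sig_b = compute_signature(moved, key[0], key[1], wt, mt, **kwargs)
        # pair counts are integers: rotation must not move any pair across a cutoff
        assert (sig_a.features == sig_b.features).all()

    def test_wild_type_mismatch_raises(self, cloud_structure, table):
        key, wt, _ = self._a_site(cloud_structure)
        wrong = "G" if wt != "G" else "A"
        with pytest.raises(WildTypeMismatchError):
            compute_signature(cloud_structure, key[0], key[1], wrong, "W", table=table, rsa=0.1)

    def test_intra_residue_exclusion_reduces_counts(self, cloud_structure, table):
        key, wt, mt = self._a_site(cloud_structure)
        kwargs = dict(table=table, ph=7.0, temperature=25.0, rsa=0.2)
        full = compute_signature(
            cloud_structure, key[0], key[1], wt, mt,
            params=SignatureParams(include_intra_residue=True), **kwargs,
        )
        reduced = compute_signature(
            cloud_structure, key[0], key[1], wt, mt,
            params=SignatureParams(include_intra_residue=False), **kwargs,
        )
        n_scan = 21 * 40
        assert (reduced.features[:n_scan] <= full.features[:n_scan]).all()
        assert (reduced.features[:n_scan] < full.features[:n_scan]).any()
        assert (reduced.features[n_scan:] == full.features[n_scan:]).all()
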
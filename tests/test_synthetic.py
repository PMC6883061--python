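"""Ground-truth properties of the synthetic fibril, nanoparticle and
trajectory generators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibnp import (DriftSpec, FibrilSpec, NPSpec, build_fibril,
                   build_nanoparticle, compute_twist_report,
                   icosahedral_gold_shell, invert_charge_sequence, place_near,
                   synthesize_trajectory)
from fibnp.model import select
from fibnp.synthetic import NP_RECIPES, fibonacci_sphere
from fibnp.twist import peptide_vector


class TestFibril:
    def test_axial_span_is_13_44_nm(self, fibril_6p48):
        z = fibril_6p48.positions[:, 2]
        span = z.max() - z.min()
        assert span == pytest.approx(28 * 4.8)
        assert 130.0 <= span <= 140.0  # inside the 13-14 nm window

    def test_untwisted_marker_vectors_are_parallel(self):
        f = build_fibril(FibrilSpec(imposed_twist=0.0))
        vecs = [peptide_vector(f, f.positions, 0, j) for j in range(1, 30)]
        v0 = vecs[0] / np.linalg.norm(vecs[0])
        for v in vecs[1:]:
            assert np.allclose(v / np.linalg.norm(v), v0, atol=1e-12)
        assert abs(v0[2]) < 1e-9  # perpendicular to the fibril axis

    @pytest.mark.parametrize("theta", [3.0, 6.48, 12.0])
    def test_consecutive_vectors_related_by_axis_rotation(self, theta):
        f = build_fibril(FibrilSpec(imposed_twist=theta,
                                    n_peptides_per_protofilament=4))
        t = np.radians(theta)
        rz = np.array([[np.cos(t), -np.sin(t), 0],
                       [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
        for j in range(1, 4):
            v1 = peptide_vector(f, f.positions, 0, j)
            v2 = peptide_vector(f, f.positions, 0, j + 1)
            assert np.allclose(v2, rz @ v1, atol=1e-9)

    def test_charges_follow_residue_table(self, fibril_6p48):
        f = fibril_6p48
        # Glu22/Asp23 sidechain beads carry -1; Lys16 +1; backbone 0
        cb = f.names == "CB"
        assert np.all(f.charges[(f.res_seq == 22) & cb] == -1.0)
        assert np.all(f.charges[(f.res_seq == 23) & cb] == -1.0)
        assert np.all(f.charges[(f.res_seq == 16) & cb] == 1.0)
        assert np.all(f.charges[f.names == "CA"] == 0.0)
        # whole fibril is net negative like the real peptide (-3 e each)
        assert f.charges.sum() == -3.0 * 58

    def test_disordered_stub_only_moves_first_eight_residues(self):
        ref = build_fibril(FibrilSpec(rng_seed=4))
        stub = build_fibril(FibrilSpec(include_disordered_stub=True, rng_seed=4))
        ordered = ref.res_seq > 8
        assert np.array_equal(ref.positions[ordered], stub.positions[ordered])
        assert not np.allclose(ref.positions[~ordered], stub.positions[~ordered])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FibrilSpec(n_peptides_per_protofilament=1)
        with pytest.raises(ValueError):
            FibrilSpec(rise=-1.0)
        with pytest.raises(ValueError):
            FibrilSpec(imposed_twist=180.0)


class TestNanoparticle:
    def test_gold_bonds_all_at_rigid_length(self):
        coords, bonds = icosahedral_gold_shell(22.0, 2.74)
        d = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)
        assert np.all(np.abs(d - 2.74) < 1e-6)
        assert len(coords) == 162  # frequency-4 icosahedral shell

    @pytest.mark.parametrize("recipe,expected", [
        ("Pos", {"Pos-lig": 90}),
        ("PosNQ", {"Pos-lig": 80, "Neu-lig": 10}),
        ("Pep", {"Pep-lig": 90}),
        ("Janus", {"Pos-lig": 45, "Neg-lig": 45}),
        ("NegNQ", {"Neg-lig": 80, "Neu-lig": 10}),
    ])
    def test_recipes_have_ninety_ligands(self, recipe, expected):
        m = build_nanoparticle(NPSpec.from_recipe(recipe))
        assert len(m.ligand_map) == 90
        counts = {}
        for ltype, _ in m.ligand_map.values():
            counts[ltype] = counts.get(ltype, 0) + 1
        assert counts == expected

    @pytest.mark.parametrize("recipe,net", [
        ("Pos", 90.0), ("PosNQ", 80.0), ("NegNQ", -80.0),
        ("Janus", 0.0), ("Pep", 90.0),
    ])
    def test_net_charges(self, recipe, net):
        m = build_nanoparticle(NPSpec.from_recipe(recipe))
        assert m.charges.sum() == pytest.approx(net)

    def test_gold_core_is_neutral_and_unligated(self, pos_np):
        au = select(pos_np, element="AU")
        assert np.all(pos_np.charges[au] == 0.0)
        for _, idx in pos_np.ligand_map.values():
            assert np.intersect1d(au, idx).size == 0

    def test_janus_hemispheres_separated_by_a_plane(self):
        m = build_nanoparticle(NPSpec.from_recipe("Janus"))
        z_by_type = {"Pos-lig": [], "Neg-lig": []}
        for ltype, idx in m.ligand_map.values():
            anchor = m.positions[idx[0]]  # thiol anchor, radial direction
            z_by_type[ltype].append(anchor[2])
        hi, lo = sorted(z_by_type, key=lambda t: -np.mean(z_by_type[t]))
        assert min(z_by_type[hi]) > max(z_by_type[lo])

    def test_composition_must_sum_to_n_ligands(self):
        with pytest.raises(ValueError, match="composition sums"):
            NPSpec(composition={"Pos-lig": 50})

    def test_janus_requires_two_types(self):
        with pytest.raises(ValueError, match="two ligand types"):
            NPSpec(placement="janus", composition={"Pos-lig": 90})

    def test_fibonacci_lattice_is_deterministic_and_spread(self):
        a = fibonacci_sphere(90)
        assert np.array_equal(a, fibonacci_sphere(90))
        assert np.allclose(np.linalg.norm(a, axis=1), 1.0)
        # roughly isotropic: mean direction near zero
        assert np.linalg.norm(a.mean(axis=0)) < 0.05


class TestChargeInversion:
    def test_fibril_motif_maps_to_pep_ligand_body(self):
        motif = ["LYS", "LEU", "VAL", "PHE", "PHE", "ALA", "GLU", "ASP"]
        assert invert_charge_sequence(motif) == \
            ["GLU", "LEU", "VAL", "PHE", "PHE", "ALA", "LYS", "LYS"]

    def test_neutral_residues_unchanged(self):
        assert invert_charge_sequence(["GLY"] * 5) == ["GLY"] * 5

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            invert_charge_sequence(["XXX"])

    @given(st.lists(st.sampled_from(["LYS", "GLU"]), min_size=1, max_size=12))
    def test_involution_on_lys_glu_sequences(self, seq):
        assert invert_charge_sequence(invert_charge_sequence(seq)) == seq


class TestTrajectorySynthesis:
    def test_noiseless_frames_identical_and_span_5ns(self, fibril_small):
        t = synthesize_trajectory(fibril_small, 500, noise_sigma=0.0)
        assert t.duration_ps == 5000.0
        assert np.array_equal(t.frames[0], t.frames[-1])

    def test_same_seed_bit_identical(self, fibril_small):
        t1 = synthesize_trajectory(fibril_small, 4, 0.3, rng_seed=9)
        t2 = synthesize_trajectory(fibril_small, 4, 0.3, rng_seed=9)
        assert np.array_equal(t1.frames, t2.frames)
        t3 = synthesize_trajectory(fibril_small, 4, 0.3, rng_seed=10)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_negative_noise_rejected(self, fibril_small):
        with pytest.raises(ValueError, match="noise_sigma"):
            synthesize_trajectory(fibril_small, 2, noise_sigma=-0.1)

    def test_drift_translates_only_tagged_atoms(self, fibril_small):
        idx = np.arange(10)
        drift = DriftSpec(atom_indices=idx, translation_per_frame=(1.0, 0, 0))
        t = synthesize_trajectory(fibril_small, 3, drift=drift)
        moved = t.frames[2, idx] - t.frames[0, idx]
        assert np.allclose(moved, [2.0, 0.0, 0.0])
        rest = np.arange(10, fibril_small.n_atoms)
        assert np.array_equal(t.frames[2, rest], t.frames[0, rest])

    def test_frame_mean_twist_concentrates_with_more_frames(self):
        """Monte-Carlo convergence: the sd of frame-mean twist shrinks
        roughly as 1/sqrt(m) when pooling frames under coordinate noise."""
        f = build_fibril(FibrilSpec(imposed_twist=6.48))
        t = synthesize_trajectory(f, 200, noise_sigma=0.3, rng_seed=2)
        rep = compute_twist_report(t, last_n_frames=200)
        means = rep.frame_means
        sd_frame = means.std()
        # mean of 50-frame blocks scatters ~sqrt(50) tighter
        blocks = means.reshape(4, 50).mean(axis=1)
        assert blocks.std() < sd_frame / 3.0
        # unsigned angles under noise are upward-biased but stay close
        assert 6.48 < means.mean() < 6.48 + 0.2


class TestPlacement:
    def test_place_near_respects_gap(self, fibril_small, pos_np):
        target = select(fibril_small, residue_seq=(22, 23))
        moved = place_near(pos_np, fibril_small, target, gap=3.0)
        from scipy.spatial import cKDTree
        d = cKDTree(fibril_small.positions).query(moved.positions)[0].min()
        assert d == pytest.approx(3.0, abs=0.5)

    def test_empty_target_rejected(self, fibril_small, pos_np):
        with pytest.raises(ValueError, match="empty"):
            place_near(pos_np, fibril_small, np.array([], dtype=int))
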
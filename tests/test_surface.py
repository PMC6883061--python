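"""Stochastic SASA, contact areas and contact counting."""

import numpy as np
import pytest
from scipy.stats import chi2

from fibnp import (FibrilSpec, build_fibril, compute_sasa, contact_area,
                   count_contacts, binding_profile, synthesize_trajectory)
from fibnp.model import NonbondedParams, Trajectory, select

from conftest import toy_model


def two_sphere_exact(r, probe, d):
    """Exposed area of two identical probe-expanded spheres at distance d:
    each loses a spherical cap of height h = R - d/2."""
    R = r + probe
    h = R - d / 2.0
    return 2.0 * (4.0 * np.pi * R * R - 2.0 * np.pi * R * h)


class TestComputeSasa:
    def test_isolated_sphere_is_exact(self, params):
        res = compute_sasa(np.zeros((1, 3)), [1.7], params)
        assert res.total_area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-12)
        assert res.mc_se == 0.0

    def test_fully_buried_atom_is_zero(self, params):
        res = compute_sasa(np.zeros((1, 3)), [1.0], params,
                           occluder_positions=np.zeros((1, 3)),
                           occluder_radii=[10.0])
        assert res.total_area == 0.0

    def test_two_sphere_cap_formula_within_mc_error(self, params):
        exact = two_sphere_exact(1.7, 1.4, 3.0)
        res = compute_sasa(np.array([[0, 0, 0], [3.0, 0, 0.0]]),
                           [1.7, 1.7], params)
        assert abs(res.total_area - exact) <= 3.0 * res.mc_se

    def test_total_is_sum_of_per_atom(self, params):
        pos = np.random.default_rng(0).uniform(0, 8, (20, 3))
        res = compute_sasa(pos, np.full(20, 1.7), params)
        assert res.total_area == pytest.approx(res.per_atom_area.sum())
        caps = 4 * np.pi * (1.7 + params.probe_radius) ** 2
        assert np.all(res.per_atom_area <= caps + 1e-9)

    def test_missing_radius_is_loud(self, params):
        with pytest.raises(ValueError, match="radii"):
            compute_sasa(np.zeros((1, 3)), [np.nan], params)

    def test_seed_reproducibility(self):
        pos = np.random.default_rng(1).uniform(0, 6, (8, 3))
        r = np.full(8, 1.7)
        a = compute_sasa(pos, r, NonbondedParams(rng_seed=5))
        b = compute_sasa(pos, r, NonbondedParams(rng_seed=5))
        c = compute_sasa(pos, r, NonbondedParams(rng_seed=6))
        assert a.total_area == b.total_area
        assert a.total_area != c.total_area

    def test_rigid_rotation_changes_area_only_within_mc_error(self):
        pos = np.random.default_rng(2).uniform(0, 6, (10, 3))
        r = np.full(10, 1.6)
        p = NonbondedParams(rng_seed=3)
        a = compute_sasa(pos, r, p)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        b = compute_sasa(pos @ rot.T + 7.0, r, p)
        se = np.hypot(a.mc_se, b.mc_se)
        assert abs(a.total_area - b.total_area) <= 4.0 * se

    def test_error_scatter_is_consistent_with_binomial_se(self):
        """50 replicate 500-point estimates scatter around the high-resolution
        reference with chi-square-consistent spread (alpha = 0.01)."""
        pos = np.random.default_rng(7).uniform(0, 5, (5, 3))
        r = np.full(5, 1.7)
        ref = compute_sasa(pos, r, NonbondedParams(rng_seed=0,
                                                   sasa_points=10 ** 6))
        z2 = []
        for seed in range(50):
            est = compute_sasa(pos, r, NonbondedParams(rng_seed=100 + seed))
            z2.append(((est.total_area - ref.total_area) / est.mc_se) ** 2)
        stat = float(np.sum(z2))
        assert chi2.ppf(0.005, 50) < stat < chi2.ppf(0.995, 50)

    def test_bare_occluder_surface_exposes_more(self, params):
        from dataclasses import replace
        pos = np.array([[0.0, 0, 0]])
        occ = np.array([[3.5, 0, 0]])
        expanded = compute_sasa(pos, [1.7], params,
                                occluder_positions=occ, occluder_radii=[1.7])
        bare = compute_sasa(pos, [1.7], replace(params, occluder_surface="bare"),
                            occluder_positions=occ, occluder_radii=[1.7])
        assert bare.total_area >= expanded.total_area


@pytest.fixture(scope="module")
def small_system():
    f = build_fibril(FibrilSpec(n_peptides_per_protofilament=5,
                                imposed_twist=6.48))
    traj = synthesize_trajectory(f, 4, noise_sigma=0.1, rng_seed=6)
    return f, traj


class TestContactArea:

    def test_distant_context_gives_zero_area(self, small_system, params):
        f, traj = small_system
        n = f.n_atoms
        half = np.arange(n // 2)
        far = np.arange(n // 2, n)
        shifted = Trajectory(f, traj.frames.copy())
        shifted.frames[:, far] += 100.0
        res = contact_area(half, far, shifted, params, last_n_frames=4)
        assert abs(res.contact_area) <= 3.0 * res.mc_se + 1e-9

    def test_full_context_occludes_at_least_its_subset(self, small_system, params):
        f, traj = small_system
        np_sel = select(f, chain=f.peptides[0].chain_id)
        rest = np.setdiff1d(np.arange(f.n_atoms), np_sel)
        beta = np.intersect1d(rest, select(f, residue_seq=(12, 40)))
        full = contact_area(np_sel, rest, traj, params, last_n_frames=4)
        sub = contact_area(np_sel, beta, traj, params, last_n_frames=4)
        # same points, occluder superset: monotone per construction
        assert full.contact_area >= sub.contact_area - 1e-9
        assert full.sasa_alone == pytest.approx(sub.sasa_alone)

    def test_overlapping_selections_rejected(self, small_system, params):
        f, traj = small_system
        with pytest.raises(ValueError, match="overlap"):
            contact_area(np.arange(10), np.arange(5, 15), traj, params,
                         last_n_frames=4)

    def test_matches_high_resolution_self_oracle(self, params):
        """Half-buried cluster against a dense slab: the 500-point estimate
        agrees with a 10^6-point reference within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        cluster = rng.uniform(0, 6, (6, 3)) + np.array([0, 0, 4.0])
        slab = rng.uniform(0, 10, (60, 3)) * np.array([1, 1, 0.3])
        m = toy_model(np.vstack([cluster, slab]), vdw_radii=[1.7] * 66)
        traj = Trajectory(m, m.positions[None, :, :])
        a = np.arange(6)
        b = np.arange(6, 66)
        est = contact_area(a, b, traj, params, last_n_frames=1)
        hi = contact_area(a, b, traj,
                          NonbondedParams(rng_seed=0, sasa_points=10 ** 6),
                          last_n_frames=1)
        assert abs(est.contact_area - hi.contact_area) <= 3.0 * est.mc_se


class TestCountContacts:
    def test_boundary_is_inclusive(self):
        m = toy_model([[0, 0, 0], [5.0, 0, 0]])
        assert count_contacts(m, [0], [1], m.positions, cutoff=5.0) == 1
        m2 = toy_model([[0, 0, 0], [5.001, 0, 0]])
        assert count_contacts(m2, [0], [1], m2.positions, cutoff=5.0) == 0

    def test_distant_groups_give_zero(self):
        m = toy_model([[0, 0, 0], [20.0, 0, 0]])
        assert count_contacts(m, [0], [1], m.positions) == 0

    def test_hydrogens_excluded_by_default(self):
        m = toy_model([[0, 0, 0], [1, 0, 0], [3, 0, 0]],
                      elements=["H", "C", "C"])
        assert count_contacts(m, [0, 1], [2], m.positions) == 1
        assert count_contacts(m, [0, 1], [2], m.positions, heavy_only=False) == 2

    def test_overlap_rejected(self):
        m = toy_model(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="overlap"):
            count_contacts(m, [0, 1], [1, 2], m.positions)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 20, (100, 3))
        m = toy_model(pos)
        a, b = np.arange(50), np.arange(50, 100)
        fast = count_contacts(m, a, b, pos, cutoff=5.0)
        slow = 0
        for i in a:
            if any(np.linalg.norm(pos[i] - pos[j]) <= 5.0 for j in b):
                slow += 1
        assert fast == slow


class TestBindingProfile:
    def test_far_peptides_count_zero(self, params):
        f = build_fibril(FibrilSpec(n_peptides_per_protofilament=3))
        probe = toy_model(np.full((4, 3), 500.0), chain_ids=["Z"] * 4,
                          role_tag="nanoparticle")
        from fibnp.model import concat_models
        sys_ = concat_models([f, probe])
        traj = synthesize_trajectory(sys_, 2)
        peps = [sys_.peptide_atom_indices(p) for p in sys_.peptides]
        np_sel = np.arange(f.n_atoms, sys_.n_atoms)
        prof = binding_profile(sys_, peps, np_sel, traj, params, last_n_frames=2)
        assert np.all(prof.means == 0.0)

    def test_constructed_contact_count_is_exact(self, params):
        # 30 heavy atoms placed 4 A from a probe atom, 10 far away
        near = np.column_stack([np.full(30, 4.0), np.arange(30) * 0.01,
                                np.zeros(30)])
        far = np.full((10, 3), 300.0)
        pep = np.vstack([near, far])
        probe = np.zeros((1, 3))
        m = toy_model(np.vstack([pep, probe]),
                      chain_ids=["A"] * 40 + ["B"])
        traj = Trajectory(m, m.positions[None, :, :])
        prof = binding_profile(m, [np.arange(40)], np.array([40]), traj,
                               params, last_n_frames=1)
        assert prof.means[0] == 30.0

    def test_noisy_mean_close_to_noiseless_count(self, params):
        near = np.column_stack([np.full(30, 4.0), np.arange(30) * 0.01,
                                np.zeros(30)])
        m = toy_model(np.vstack([near, np.zeros((1, 3))]),
                      chain_ids=["A"] * 30 + ["B"])
        traj = synthesize_trajectory(m, 200, noise_sigma=0.2, rng_seed=4)
        prof = binding_profile(m, [np.arange(30)], np.array([30]), traj,
                               params, last_n_frames=200)
        se = prof.sds[0] / np.sqrt(prof.frames_used)
        assert abs(prof.means[0] - 30.0) <= max(3.0 * se, 0.5)

    def test_empty_peptide_list_rejected(self, params):
        m = toy_model(np.zeros((2, 3)))
        traj = Trajectory(m, m.positions[None, :, :])
        with pytest.raises(ValueError, match="empty"):
            binding_profile(m, [], np.array([0]), traj, params, last_n_frames=1)
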
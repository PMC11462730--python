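"""Wavelength assignment: cost matrix, LSA, Procrustes, MCD, optimize loop."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pinklaue as pl
from pinklaue.assignment import (
    AssignmentError,
    AssignmentParams,
    NonConvergenceError,
    assign_indices,
    build_cost_matrix,
    enumerate_feasible_hkls,
    mcd_outliers,
    optimize_indexing,
    procrustes_rotation,
)
from pinklaue.geometry import (
    BeamModel,
    CrystalModel,
    UnitCell,
    axis_angle_matrix,
    misorientation_deg,
    reciprocal_basis,
)
from pinklaue.io import sequence_to_stills


def _random_dirs(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestCostMatrix:
    def test_identical_sets_have_zero_diagonal(self):
        d = _random_dirs(np.random.default_rng(0), 6)
        cost = build_cost_matrix(d, d)
        assert np.allclose(np.diag(cost), 0.0, atol=1e-7)

    def test_orthogonal_pair(self):
        cost = build_cost_matrix([[1.0, 0, 0]], [[0, 1.0, 0]])
        assert cost[0, 0] == pytest.approx(math.pi / 2)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        obs, cand = _random_dirs(rng, 5), _random_dirs(rng, 7)
        cost = build_cost_matrix(obs, cand)
        for i in range(5):
            for j in range(7):
                want = math.acos(max(-1, min(1, float(obs[i] @ cand[j]))))
                assert cost[i, j] == pytest.approx(want, abs=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = _random_dirs(rng, 4), _random_dirs(rng, 6)
        assert np.allclose(build_cost_matrix(a, b), build_cost_matrix(b, a).T)

    def test_rejects_non_unit_vectors(self):
        with pytest.raises(AssignmentError):
            build_cost_matrix([[2.0, 0, 0]], [[1.0, 0, 0]])


def _brute_force_assignment(cost):
    n, m = cost.shape
    best = math.inf
    for perm in itertools.permutations(range(m), n):
        total = sum(cost[i, j] for i, j in enumerate(perm))
        best = min(best, total)
    return best


class TestAssignIndices:
    def test_recovers_permutation(self):
        cost = np.array([[0.0, 5, 5], [5, 5, 0.0], [5, 0.0, 5]])
        rows, cols = assign_indices(cost, max_angle=1.0)
        assert list(cols[np.argsort(rows)]) == [0, 2, 1]

    def test_3x3_equals_brute_force(self):
        cost = np.array([[1.0, 2, 3], [2, 4, 6], [3, 6, 9]])
        rows, cols = assign_indices(cost, max_angle=100.0)
        assert cost[rows, cols].sum() == pytest.approx(_brute_force_assignment(cost))

    @pytest.mark.parametrize("seed", range(5))
    def test_6x8_equals_brute_force(self, seed):
        cost = np.random.default_rng(seed).uniform(size=(6, 8))
        rows, cols = assign_indices(cost, max_angle=10.0)
        assert cost[rows, cols].sum() == pytest.approx(_brute_force_assignment(cost))

    def test_releases_matches_beyond_gate(self):
        cost = np.array([[0.01, 9.0], [9.0, 0.5]])
        rows, cols = assign_indices(cost, max_angle=0.1)
        assert list(rows) == [0] and list(cols) == [0]

    def test_infeasible_when_more_observations(self):
        with pytest.raises(AssignmentError):
            assign_indices(np.ones((3, 2)), max_angle=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beaten_by_greedy(self, seed):
        cost = np.random.default_rng(100 + seed).uniform(size=(8, 12))
        rows, cols = assign_indices(cost, max_angle=10.0)
        taken, greedy = set(), 0.0
        for i in range(8):
            j = min((j for j in range(12) if j not in taken), key=lambda j: cost[i, j])
            taken.add(j)
            greedy += cost[i, j]
        assert cost[rows, cols].sum() <= greedy + 1e-12


class TestProcrustes:
    def test_identity_for_equal_sets(self):
        d = _random_dirs(np.random.default_rng(3), 20)
        assert np.allclose(procrustes_rotation(d, d), np.eye(3), atol=1e-12)

    def test_exact_recovery_of_small_rotation(self):
        d = _random_dirs(np.random.default_rng(4), 50)
        R0 = axis_angle_matrix([0.3, -0.5, 0.8], 0.3)
        R = procrustes_rotation(d, d @ R0.T)
        assert misorientation_deg(np.eye(3), R @ R0.T) < 1e-9

    def test_noisy_recovery(self):
        # sigma = 1e-3 rad of direction noise on n = 200 pairs
        rng = np.random.default_rng(5)
        d = _random_dirs(rng, 200)
        R0 = axis_angle_matrix([1.0, 2.0, -1.0], 0.3)
        obs = d @ R0.T + rng.normal(0, 1e-3, size=d.shape)
        obs /= np.linalg.norm(obs, axis=1, keepdims=True)
        R = procrustes_rotation(d, obs)
        assert misorientation_deg(np.eye(3), R @ R0.T) < 0.02

    def test_collinear_pairs_are_degenerate(self):
        d = np.tile([0.0, 0.0, 1.0], (5, 1))
        with pytest.raises(AssignmentError):
            procrustes_rotation(d, d)


class TestMCDOutliers:
    def test_single_far_point_flagged_exactly(self):
        # ten tight grid points plus one at ~100 cloud-sigma
        grid = np.array([[i % 3, i // 3] for i in range(10)], dtype=float) * 0.01
        pts = np.vstack([grid, [[1.0, 1.0]]])
        mask = mcd_outliers(pts)  # n = 11: exact subset search
        assert mask[:10].all() and not mask[10]

    def test_identical_points_fall_back_to_all_inliers(self):
        pts = np.ones((8, 2))
        with pytest.warns(UserWarning):
            mask = mcd_outliers(pts)
        assert mask.all()

    def test_gaussian_false_positive_rate(self):
        pts = np.random.default_rng(7).normal(size=(500, 2))
        flagged = 1.0 - mcd_outliers(pts).mean()
        assert flagged == pytest.approx(0.025, abs=0.015)

    def test_too_few_points_rejected(self):
        with pytest.raises(AssignmentError):
            mcd_outliers(np.zeros((3, 2)))


class TestEnumerateFeasible:
    def test_matches_brute_force_grid(self):
        cell = UnitCell(10, 10, 10)
        crystal = CrystalModel(cell=cell)
        beam = BeamModel(lambda_nominal=1.1, lambda_min=1.0, lambda_max=1.2)
        hkl, q, lam = enumerate_feasible_hkls(crystal, beam, d_min=2.0)
        got = set(map(tuple, hkl))
        B = reciprocal_basis(cell)
        want = set()
        for h in range(-6, 7):
            for k in range(-6, 7):
                for l in range(-6, 7):
                    if h == k == l == 0:
                        continue
                    qv = B @ np.array([h, k, l], float)
                    if np.linalg.norm(qv) > 0.5 or qv @ beam.s0_hat >= 0:
                        continue
                    lam_v = -2 * (qv @ beam.s0_hat) / (qv @ qv)
                    if 1.0 <= lam_v <= 1.2:
                        want.add((h, k, l))
        assert got == want

    def test_wavelengths_inside_bounds(self):
        crystal = CrystalModel(cell=UnitCell(34, 45, 99))
        beam = BeamModel()
        _, _, lam = enumerate_feasible_hkls(crystal, beam, d_min=1.4)
        assert lam.min() >= 0.9 and lam.max() <= 1.2

    def test_resolution_cutoff_beyond_cell_is_empty(self):
        crystal = CrystalModel(cell=UnitCell(10, 10, 10))
        beam = BeamModel()
        hkl, _, _ = enumerate_feasible_hkls(crystal, beam, d_min=25.0)
        assert len(hkl) == 0


class TestOptimizeIndexing:
    def test_noise_free_fixed_point(self, noise_free_mini_series):
        exp, cfg, observed, truth = noise_free_mini_series
        still = sequence_to_stills(exp).by_image()[0]
        group = observed[observed["image_id"] == 0]
        assigned, crystal, info = optimize_indexing(group, still)
        assert len(assigned) == len(group)
        audit = pl.misindexing_report(assigned, truth)
        assert audit.fraction_correct == 1.0
        dom = pl.truth_for_observed(truth)
        key = pd.MultiIndex.from_frame(assigned[["image_id", "spot_id"]])
        lam_err = np.abs(
            assigned["wavelength"].to_numpy() - dom.loc[key, "lambda_spot"].to_numpy()
        )
        assert lam_err.max() < 1e-9
        assert misorientation_deg(still.crystal.U, crystal.U) < 1e-9

    def test_recovers_perturbed_orientation(self, noise_free_mini_series):
        exp, cfg, observed, truth = noise_free_mini_series
        still = sequence_to_stills(exp).by_image()[1]
        group = observed[observed["image_id"] == 1]
        U_p = pl.perturb_orientation(still.crystal.U, 0.2, seed=9)
        perturbed = dataclasses.replace(
            still, crystal=dataclasses.replace(still.crystal, U=U_p)
        )
        assigned, crystal, info = optimize_indexing(group, perturbed)
        assert misorientation_deg(still.crystal.U, crystal.U) < 0.01
        assert pl.misindexing_report(assigned, truth).fraction_correct == 1.0

    def test_inlier_count_nondecreasing_on_noise_free_data(self, noise_free_mini_series):
        exp, cfg, observed, truth = noise_free_mini_series
        still = sequence_to_stills(exp).by_image()[2]
        group = observed[observed["image_id"] == 2]
        _, _, info = optimize_indexing(group, still)
        assert np.all(np.diff(info["n_inliers"]) >= 0)

    def test_assigned_wavelengths_and_hkls_feasible(self, noise_free_mini_series):
        exp, cfg, observed, truth = noise_free_mini_series
        still = sequence_to_stills(exp).by_image()[3]
        group = observed[observed["image_id"] == 3]
        params = AssignmentParams()
        assigned, crystal, _ = optimize_indexing(group, still, params)
        assert assigned["wavelength"].between(params.lambda_min, params.lambda_max).all()
        feas, _, _ = enumerate_feasible_hkls(
            crystal, exp.beam, params.d_min,
            lambda_min=params.lambda_min, lambda_max=params.lambda_max,
        )
        feas_set = set(map(tuple, feas))
        assert all(
            tuple(r) in feas_set
            for r in assigned[["h", "k", "l"]].to_numpy(dtype=int)
        )

    def test_too_few_spots_raises(self, noise_free_mini_series):
        exp, cfg, observed, truth = noise_free_mini_series
        still = sequence_to_stills(exp).by_image()[0]
        with pytest.raises(NonConvergenceError):
            optimize_indexing(observed.iloc[:4], still)
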
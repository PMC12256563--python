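"""Correspondence, affine estimation, rigid refinement and end-to-end runs."""

from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from helixreg.detection import DetectedFiducial, ThresholdSpec
from helixreg.errors import (
    AmbiguousCorrespondenceError,
    InsufficientFiducialsError,
    RankDeficiencyError,
)
from helixreg.phantom import ModelFiducial, PhantomGeometry, generate_model
from helixreg.registration import (
    Correspondence,
    compute_fre,
    estimate_affine,
    match_large_fiducials,
    pattern_distance_costs,
    refine_registration,
    register,
)
from helixreg.simulate import RenderConfig, render_phantom_cbct
from helixreg.transforms import (
    apply_point,
    identity,
    rotation_about_axis,
)

from conftest import random_rigid, rotation_angle_deg


def _as_detected(points, diameter=3.0):
    return [
        DetectedFiducial(centroid=np.asarray(p, float), equivalent_diameter=diameter,
                         voxel_count=100, size_class="large" if diameter >= 2.25 else "small")
        for p in points
    ]


# ---------------------------------------------------------------------------
# correspondence


class TestPatternMatching:
    def test_costs_invariant_under_rigid_motion(self, model_large):
        pts = np.array([f.center for f in model_large])
        rng = np.random.default_rng(31)
        base = pattern_distance_costs(pts[2:8], pts)
        for _ in range(10):
            t = random_rigid(rng, "p", "c")
            moved = apply_point(t, pts[2:8])
            np.testing.assert_allclose(
                pattern_distance_costs(moved, pts), base, atol=1e-9
            )

    def test_full_set_matches_identically(self, model_large):
        pts = np.array([f.center for f in model_large])
        t = random_rigid(np.random.default_rng(7), "p", "c")
        corr = match_large_fiducials(_as_detected(apply_point(t, pts)), model_large)
        assert corr.pairs == tuple((i, i) for i in range(len(model_large)))
        assert max(corr.cost_per_pair) < 1e-9

    def test_every_run_of_four_matches_correctly(self, model_large):
        pts = np.array([f.center for f in model_large])
        for start in range(len(pts) - 3):
            corr = match_large_fiducials(_as_detected(pts[start : start + 4]), model_large)
            assert corr.pairs == tuple((i, start + i) for i in range(4))

    @pytest.mark.parametrize("m", [5, 6, 7, 8])
    def test_jittered_runs_agree_with_assignment_oracle(self, model_large, m):
        pts = np.array([f.center for f in model_large])
        n = len(pts)
        rng = np.random.default_rng(100 + m)
        for _ in range(25):
            start = rng.integers(0, n - m + 1)
            truth = np.arange(start, start + m)
            jittered = pts[truth] + rng.normal(0.0, 0.1, size=(m, 3))
            corr = match_large_fiducials(_as_detected(jittered), model_large)
            assert corr.pairs == tuple((i, start + i) for i in range(m))
            costs = pattern_distance_costs(jittered, pts)
            if m <= 5:  # true exhaustive-permutation oracle
                scored = {
                    perm: costs[range(m), list(perm)].sum()
                    for perm in permutations(range(n), m)
                }
                best = min(scored, key=scored.get)
            else:  # independent global-assignment oracle
                rows, cols = linear_sum_assignment(costs)
                best = tuple(cols[np.argsort(rows)])
            assert best == tuple(truth)

    def test_too_few_large_fiducials(self, model_large):
        pts = np.array([f.center for f in model_large])[:3]
        with pytest.raises(InsufficientFiducialsError):
            match_large_fiducials(_as_detected(pts), model_large)

    def test_symmetric_pattern_raises_ambiguity(self):
        # two translated copies of the same 4-point motif: distance patterns tie
        motif = np.array([[0, 0, 0], [10, 0, 0], [25, 0, 0], [45, 0, 0]], float)
        fake_model = [
            ModelFiducial(index=i + 1, center=c, diameter=3.0, size_class="large")
            for i, c in enumerate(np.vstack([motif, motif + [0, 0, 500]]))
        ]
        with pytest.raises(AmbiguousCorrespondenceError):
            match_large_fiducials(_as_detected(motif), fake_model)

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(AmbiguousCorrespondenceError):
            Correspondence(pairs=((0, 1), (1, 1)), cost_per_pair=(0.0, 0.0))


# ---------------------------------------------------------------------------
# affine estimation


class TestAffineEstimation:
    def _identity_corr(self, m):
        return Correspondence(
            pairs=tuple((i, i) for i in range(m)), cost_per_pair=(0.0,) * m
        )

    def test_identical_points_give_identity(self, model_large):
        pts = np.array([f.center for f in model_large])
        corr = self._identity_corr(len(pts))
        t = estimate_affine(corr, _as_detected(pts), model_large)
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_recovers_generating_rigid_transform(self, model_large):
        rng = np.random.default_rng(9)
        pts = np.array([f.center for f in model_large])
        corr = self._identity_corr(len(pts))
        for _ in range(10):
            t = random_rigid(rng, "p", "c")
            est = estimate_affine(corr, _as_detected(apply_point(t, pts)), model_large)
            np.testing.assert_allclose(est.matrix, t.matrix, atol=1e-9)

    def test_recovers_affine_scale(self, model_large):
        # the affine fit must not enforce rigidity: a 2% scale is recovered
        pts = np.array([f.center for f in model_large])
        corr = self._identity_corr(len(pts))
        truth = np.eye(4)
        truth[:3, :3] *= 1.02
        truth[:3, 3] = [4.0, -2.0, 7.0]
        mapped = pts @ truth[:3, :3].T + truth[:3, 3]
        est = estimate_affine(corr, _as_detected(mapped), model_large)
        np.testing.assert_allclose(est.matrix, truth, atol=1e-9)

    def test_coplanar_configuration_rejected(self):
        flat_model = [
            ModelFiducial(index=i + 1, center=np.array([x, y, 0.0]), diameter=3.0,
                          size_class="large")
            for i, (x, y) in enumerate([(0, 0), (10, 0), (0, 10), (10, 10), (5, 5)])
        ]
        pts = np.array([f.center for f in flat_model])
        corr = self._identity_corr(len(pts))
        with pytest.raises(RankDeficiencyError):
            estimate_affine(corr, _as_detected(pts), flat_model)

    def test_too_few_pairs_rejected(self, model_large):
        corr = Correspondence(pairs=((0, 0), (1, 1), (2, 2)), cost_per_pair=(0.0,) * 3)
        pts = np.array([f.center for f in model_large])
        with pytest.raises(InsufficientFiducialsError):
            estimate_affine(corr, _as_detected(pts), model_large)


# ---------------------------------------------------------------------------
# refinement


class TestRefinement:
    def test_already_optimal_is_left_unchanged(self, model):
        truth = rotation_about_axis([1, 0.4, -0.2], 20.0, "p", "c", t=[5, 3, -8])
        detected = _as_detected(apply_point(truth, np.array([f.center for f in model])))
        refined, diag = refine_registration(truth, detected, model)
        assert diag.final_cost < 1e-6
        assert diag.converged
        assert np.linalg.norm(refined.translation - truth.translation) < 1e-3
        assert rotation_angle_deg(refined.rotation, truth.linear) < 1e-3

    def test_recovers_truth_from_perturbed_init(self, model):
        truth = rotation_about_axis([0.2, 1, 0.5], -15.0, "p", "c", t=[-4, 6, 2])
        detected = _as_detected(apply_point(truth, np.array([f.center for f in model])))
        wobble = rotation_about_axis([0, 0, 1], 2.0, "c", "c", t=[2.0, 0.0, 0.0])
        init = wobble @ truth  # 2 deg rotation + 2 mm translation off truth
        refined, diag = refine_registration(init, detected, model)
        assert np.linalg.norm(refined.translation - truth.translation) < 0.01
        assert rotation_angle_deg(refined.rotation, truth.linear) < 0.01
        assert diag.termination_reason in {"cost-tolerance", "step-tolerance"}

    def test_noise_floor_rmse(self, model):
        rng_master = np.random.default_rng(77)
        pts = np.array([f.center for f in model])
        for _ in range(20):
            truth = random_rigid(rng_master, "p", "c", max_angle_deg=30, max_translation=10)
            jitter = rng_master.normal(0.0, 0.05, size=pts.shape)
            detected = _as_detected(apply_point(truth, pts) + jitter)
            refined, diag = refine_registration(truth, detected, model)
            assert diag.final_cost <= 0.15

    def test_iteration_budget_respected(self, model):
        truth = identity("p", "c")
        detected = _as_detected(np.array([f.center for f in model]))
        _, diag = refine_registration(truth, detected, model, max_iterations=3)
        assert diag.iterations <= 3

    def test_cost_never_increases(self, model):
        truth = rotation_about_axis([1, 1, 1], 10.0, "p", "c", t=[3, 3, 3])
        pts = np.array([f.center for f in model])
        detected = _as_detected(apply_point(truth, pts) + 0.3)
        _, diag = refine_registration(truth, detected, model)
        assert diag.final_cost <= diag.initial_cost + 1e-12


# ---------------------------------------------------------------------------
# FRE


class TestFre:
    def test_perfect_alignment_is_zero(self, model):
        t = random_rigid(np.random.default_rng(1), "p", "c")
        detected = _as_detected(apply_point(t, np.array([f.center for f in model])))
        assert compute_fre(t, detected, model) < 1e-12

    def test_single_pair(self, model):
        detected = _as_detected([model[0].center + [0.1, 0.0, 0.0]])
        fre = compute_fre(identity("p", "c"), detected, [model[0]], pairs=[(0, 0)])
        assert abs(fre - 0.1) < 1e-12

    def test_hand_rmse(self, model):
        detected = _as_detected(
            [model[0].center + [0.1, 0, 0], model[1].center + [0, 0.2, 0]]
        )
        fre = compute_fre(identity("p", "c"), detected, model[:2], pairs=[(0, 0), (1, 1)])
        assert abs(fre - np.sqrt((0.01 + 0.04) / 2)) < 1e-12

    def test_no_pairs_rejected(self, model):
        with pytest.raises(InsufficientFiducialsError):
            compute_fre(identity("p", "c"), [], model)


# ---------------------------------------------------------------------------
# end-to-end


TRUNCATED_POSE = rotation_about_axis(
    [-0.01399, 0.355693, 0.934498], 2.3388, "p", "c", t=[10.8833, -37.2739, -3.8272]
)


class TestEndToEnd:
    def test_register_recovers_known_pose(self, model):
        truth = rotation_about_axis([0.3, 0.5, 1.0], 12.0, "p", "c", t=[3, -2, 5])
        cfg = RenderConfig(voxel_size=0.5, noise_sigma=10.0, seed=1)
        vol, _ = render_phantom_cbct(model, truth, cfg)
        result = register(vol, model, identity("r", "e"), identity("e", "p"))
        assert np.linalg.norm(result.tp2c_refined.translation - truth.translation) < 0.2
        assert rotation_angle_deg(result.tp2c_refined.rotation, truth.linear) < 0.1
        assert result.fre <= 0.15
        assert result.n_large_used == 8
        assert result.converged

    def test_truncated_scene_succeeds(self, model):
        # worst observed coverage: only 7 large + 14 small fiducials visible
        cfg = RenderConfig(voxel_size=0.5, noise_sigma=10.0, seed=3)
        vol, truth = render_phantom_cbct(model, TRUNCATED_POSE, cfg)
        assert truth.visible.sum() == 21
        result = register(vol, model, identity("r", "e"), identity("e", "p"))
        assert result.n_large_used == 7
        assert result.n_small_used == 14
        assert np.linalg.norm(
            result.tp2c_refined.translation - TRUNCATED_POSE.translation
        ) < 0.2
        assert rotation_angle_deg(result.tp2c_refined.rotation, TRUNCATED_POSE.linear) < 0.1
        assert result.fre <= 0.15

    def test_three_large_scene_rejected(self):
        geometry = PhantomGeometry(
            n_small=29, n_large=3, large_indices=(1, 16, 32)
        )
        model3 = generate_model(geometry)
        cfg = RenderConfig(voxel_size=1.0, noise_sigma=10.0, seed=5)
        vol, _ = render_phantom_cbct(model3, identity("p", "c"), cfg)
        with pytest.raises(InsufficientFiducialsError):
            register(
                vol, model3, identity("r", "e"), identity("e", "p"),
                ThresholdSpec(mode="expected-volume"),
            )

    def test_chained_tr2c_includes_robot_pose(self, model):
        truth = rotation_about_axis([0.1, 0.9, 0.2], 8.0, "p", "c", t=[2, 1, -3])
        cfg = RenderConfig(voxel_size=0.5, noise_sigma=10.0, seed=11)
        vol, _ = render_phantom_cbct(model, truth, cfg)
        rng = np.random.default_rng(12)
        tr2e = random_rigid(rng, "r", "e")
        te2p = random_rigid(rng, "e", "p")
        result = register(vol, model, tr2e, te2p)
        expected = result.tp2c_refined.as_homogeneous("p", "c") @ te2p @ tr2e
        np.testing.assert_allclose(result.tr2c.matrix, expected.matrix, atol=1e-12)
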
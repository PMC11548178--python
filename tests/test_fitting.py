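"""Rigid estimation, robust losses, and articulated pose fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from geoclique.bodymodel import (
    ArticulatedModel,
    PoseParams,
    joint_angle_errors,
    pose_model,
)
from geoclique.features import Correspondence, CorrespondenceSet
from geoclique.fitting import (
    DegenerateRigidError,
    FitConfig,
    estimate_rigid,
    evaluate_hypothesis,
    fit_pose,
    geman_mcclure,
    register,
)
from geoclique.cliques import CliqueHypothesis
from geoclique.mesh import InputError


class TestPoseModel:
    def test_zero_pose_reproduces_template(self, toy_model):
        out = pose_model(toy_model, PoseParams.rest(toy_model.n_joints))
        assert np.array_equal(out, toy_model.template_vertices)

    def test_global_rigid_equivariance(self, toy_model):
        R = Rotation.from_rotvec([0.3, -0.1, 0.7]).as_matrix()
        t = np.array([1.0, 2.0, -0.5])
        out = pose_model(toy_model, PoseParams(np.zeros((16, 3)), R, t))
        assert np.allclose(out, toy_model.template_vertices @ R.T + t)

    def test_elbow_bend_rotates_distal_bones_exactly(self, toy_model):
        theta = np.zeros((16, 3))
        theta[5] = [0.0, 0.0, np.pi / 2]  # left elbow
        out = pose_model(toy_model, PoseParams(theta))
        distal = np.isin(toy_model.part_labels, [5, 6])
        center = toy_model.joint_positions[5]
        Rz = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        expect = (toy_model.template_vertices[distal] - center) @ Rz.T + center
        assert np.abs(out[distal] - expect).max() < 1e-12
        # everything not downstream of the elbow is untouched
        rest = ~distal
        assert np.array_equal(out[rest], toy_model.template_vertices[rest])

    def test_soft_weights_blend_transforms(self):
        # two-bone chain with one half-and-half vertex
        model = ArticulatedModel(
            template_vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [1.5, 0.5, 0]],
            faces=np.empty((0, 3)),
            joint_positions=[[0, 0, 0], [1, 0, 0]],
            parents=[-1, 0],
            skinning_weights=[[1, 0], [1, 0], [0, 1], [0.5, 0.5]],
            part_labels=[0, 0, 1, 1],
            torso_label_ids=(0,),
        )
        theta = np.zeros((2, 3))
        theta[1] = [0, 0, np.pi / 2]
        out = pose_model(model, PoseParams(theta))
        v = np.array([1.5, 0.5, 0.0])
        moved = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix() @ (v - [1, 0, 0]) + [1, 0, 0]
        assert np.allclose(out[3], 0.5 * v + 0.5 * moved)

    def test_dimension_mismatch_rejected(self, toy_model):
        with pytest.raises(InputError):
            pose_model(toy_model, PoseParams(np.zeros((4, 3))))


class TestEstimateRigid:
    def test_identity_on_equal_sets(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        R, t = estimate_rigid(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_recovers_planted_rotation(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.normal(size=(15, 3))
        Rstar = Rotation.random(random_state=seed).as_matrix()
        tstar = rng.normal(size=3)
        R, t = estimate_rigid(Q, Q @ Rstar.T + tstar)
        assert np.abs(R - Rstar).max() < 1e-8
        assert np.abs(t - tstar).max() < 1e-8

    def test_near_planar_noise_keeps_proper_rotation(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(30, 3))
        Q[:, 2] *= 1e-6  # nearly planar: reflection-tempting
        Rstar = Rotation.random(random_state=2).as_matrix()
        P = Q @ Rstar.T + rng.normal(scale=1e-4, size=Q.shape)
        R, _ = estimate_rigid(Q, P)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_globally_minimal_residual(self):
        rng = np.random.default_rng(3)
        Q = rng.normal(size=(12, 3))
        P = Q @ Rotation.random(random_state=4).as_matrix().T + rng.normal(scale=0.1, size=Q.shape)
        R, t = estimate_rigid(Q, P)
        best = np.linalg.norm(P - (Q @ R.T + t))
        for k in range(1000):
            Rr = Rotation.random(random_state=1000 + k).as_matrix()
            tr = P.mean(0) - Rr @ Q.mean(0)
            assert np.linalg.norm(P - (Q @ Rr.T + tr)) >= best - 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateRigidError, match="3 pairs"):
            estimate_rigid([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateRigidError, match="rank"):
            estimate_rigid(line, line * 2 - line)  # collinear configuration


class TestGemanMcclure:
    def test_values(self):
        assert geman_mcclure(0.0, 1e-3) == 0.0
        sigma = 0.37
        assert geman_mcclure(np.sqrt(sigma), sigma) == pytest.approx(0.5)
        assert geman_mcclure(1000.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_increasing_and_bounded(self):
        s = np.linspace(0, 10, 200)
        rho = geman_mcclure(s, 1e-3)
        assert (np.diff(rho) > 0).all()
        assert rho.max() < 1.0

    def test_sigma_contract(self):
        with pytest.raises(InputError):
            geman_mcclure(1.0, 0.0)


def synthetic_fit_case(toy_model, seed, n_corr=400, magnitude=0.6):
    rng = np.random.default_rng(seed)
    theta = np.zeros((toy_model.n_joints, 3))
    nonroot = [j for j in range(toy_model.n_joints) if j != toy_model.root]
    theta[nonroot] = rng.uniform(-magnitude, magnitude, (len(nonroot), 3))
    target = pose_model(toy_model, PoseParams(theta))
    ids = rng.choice(toy_model.n_vertices, n_corr, replace=False)
    return theta, ids, target


class TestFitPose:
    def test_noiseless_recovery_from_rest(self, toy_model):
        theta, ids, target = synthetic_fit_case(toy_model, seed=0)
        res = fit_pose(
            toy_model, ids, target[ids], PoseParams.rest(16),
            FitConfig(max_iterations=400),
        )
        errs = joint_angle_errors(res.pose.theta, theta, exclude=(toy_model.root,))
        assert np.median(np.radians(errs)) < 1e-2
        # mean residual implied by the bounded data term stays below 0.1 mm
        mean_resid = np.sqrt(res.data_term / len(ids) * 1e-3)
        assert mean_resid < 1e-4

    def test_rest_pose_is_fixed_point(self, toy_model):
        ids = np.arange(0, toy_model.n_vertices, 5)
        res = fit_pose(
            toy_model, ids, toy_model.template_vertices[ids],
            PoseParams.rest(16), FitConfig(),
        )
        assert res.data_term < 1e-9
        assert np.abs(res.pose.theta).max() < 1e-3

    def test_loss_decomposition_identity(self, toy_model):
        theta, ids, target = synthetic_fit_case(toy_model, seed=1, n_corr=100)
        cfg = FitConfig()
        res = fit_pose(toy_model, ids, target[ids], PoseParams.rest(16), cfg)
        assert res.total_loss == pytest.approx(
            res.data_term + cfg.lambda_prior * res.prior_term, abs=1e-9
        )

    def test_final_stage_loss_monotone(self, toy_model):
        theta, ids, target = synthetic_fit_case(toy_model, seed=2, n_corr=120)
        res = fit_pose(toy_model, ids, target[ids], PoseParams.rest(16), FitConfig())
        h = res.loss_history
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))

    def test_robust_beats_squared_loss_under_outliers(self, toy_model):
        theta, ids, target = synthetic_fit_case(toy_model, seed=3, n_corr=300)
        rng = np.random.default_rng(99)
        pts = target[ids].copy()
        n_out = len(ids) * 3 // 10
        corrupt = rng.choice(len(ids), n_out, replace=False)
        pts[corrupt] = target[rng.choice(toy_model.n_vertices, n_out)]
        robust = fit_pose(toy_model, ids, pts, PoseParams.rest(16), FitConfig())
        squared = fit_pose(
            toy_model, ids, pts, PoseParams.rest(16), FitConfig(robust=False)
        )
        e_r = np.median(joint_angle_errors(robust.pose.theta, theta, exclude=(0,)))
        e_s = np.median(joint_angle_errors(squared.pose.theta, theta, exclude=(0,)))
        assert e_s / e_r > 3.0

    def test_fd_gradient_matches_analytic_recovery(self, toy_model):
        theta, ids, target = synthetic_fit_case(toy_model, seed=4, n_corr=200, magnitude=0.3)
        fd = fit_pose(
            toy_model, ids, target[ids], PoseParams.rest(16),
            FitConfig(gradient="fd", max_iterations=300),
        )
        errs = joint_angle_errors(fd.pose.theta, theta, exclude=(toy_model.root,))
        assert np.median(np.radians(errs)) < 2e-2

    def test_empty_correspondences_rejected(self, toy_model):
        with pytest.raises(InputError):
            fit_pose(toy_model, [], np.empty((0, 3)), PoseParams.rest(16))


class TestEvaluateHypothesis:
    def _result(self, toy_model, pose=None):
        pose = pose or PoseParams.rest(16)
        from geoclique.fitting import RegistrationResult

        return RegistrationResult(
            pose=pose,
            deformed_vertices=pose_model(toy_model, pose),
            data_term=0.0, prior_term=0.0, total_loss=0.0,
        )

    def test_subset_of_vertices_scores_zero(self, toy_model):
        res = self._result(toy_model)
        data = toy_model.template_vertices[::7]
        assert evaluate_hypothesis(res, data) == 0.0

    def test_single_point_arithmetic(self, toy_model):
        res = self._result(toy_model)
        v0 = toy_model.template_vertices[0]
        d = evaluate_hypothesis(res, [v0 + [0.0, 0.0, 0.1]])
        # 0.1 m offset may have a nearer vertex than v0; never more than 0.01
        assert 0 < d <= 0.01 + 1e-12

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        from geoclique.fitting import RegistrationResult

        model_pts = rng.normal(size=(400, 3))
        data = rng.normal(size=(500, 3))
        res = RegistrationResult(
            pose=None, deformed_vertices=model_pts,
            data_term=0, prior_term=0, total_loss=0,
        )
        fast = evaluate_hypothesis(res, data, sample_size=None)
        brute = sum(
            min(np.sum((p - m) ** 2) for m in model_pts) for p in data
        )
        assert fast == pytest.approx(brute, rel=1e-12)

    def test_empty_data_rejected(self, toy_model):
        with pytest.raises(InputError):
            evaluate_hypothesis(self._result(toy_model), np.empty((0, 3)))


class TestRegister:
    def _corrs_and_hypotheses(self, toy_model, seed=0):
        rng = np.random.default_rng(seed)
        theta = np.zeros((16, 3))
        theta[1:] = rng.uniform(-0.4, 0.4, (15, 3))
        target = pose_model(toy_model, PoseParams(theta))
        ids = rng.choice(toy_model.n_vertices, 120, replace=False)
        good = CorrespondenceSet(
            [Correspondence(int(s), int(s), 0.0) for s in ids]
        )
        return theta, target, ids, good

    def test_single_inlier_hypothesis_wins(self, toy_model):
        theta, target, ids, corrs = self._corrs_and_hypotheses(toy_model)
        hyp = CliqueHypothesis(tuple(range(len(ids))), 10.0, 0)
        best, ranked = register(
            toy_model, target, [hyp], corrs, nn_refine_iters=0
        )
        assert best.hypothesis_id == 0
        assert best.refined

    def test_inlier_hypothesis_beats_corrupted_one(self, toy_model):
        theta, target, ids, corrs = self._corrs_and_hypotheses(toy_model, seed=1)
        rng = np.random.default_rng(7)
        items = list(corrs.items)
        half = len(items) // 2
        # corrupt the second half of the correspondence list
        for i in range(half, len(items)):
            c = items[i]
            items[i] = Correspondence(
                c.source_vertex, int(rng.integers(toy_model.n_vertices)), 0.0
            )
        mixed = CorrespondenceSet(items)
        h_good = CliqueHypothesis(tuple(range(half)), 5.0, 0)
        h_bad = CliqueHypothesis(tuple(range(len(items))), 9.0, 1)
        best, ranked = register(
            toy_model, target, [h_good, h_bad], mixed,
            refine_with_all=False,
        )
        assert best.hypothesis_id == 0
        assert ranked[0].d_knn <= ranked[1].d_knn

    def test_missing_torso_falls_back_flagged(self, toy_model):
        theta, target, ids, _ = self._corrs_and_hypotheses(toy_model, seed=2)
        # restrict correspondences to the left arm: no torso labels at all
        arm = np.nonzero(np.isin(toy_model.part_labels, [4, 5, 6]))[0][:30]
        corrs = CorrespondenceSet(
            [Correspondence(int(s), int(s), 0.0) for s in arm]
        )
        hyp = CliqueHypothesis(tuple(range(len(arm))), 1.0, 0)
        best, _ = register(
            toy_model, target, [hyp], corrs,
            refine_with_all=False,
        )
        assert best.rigid_fallback

    def test_empty_hypotheses_rejected(self, toy_model):
        with pytest.raises(InputError):
            register(toy_model, toy_model.template_vertices, [],
                     CorrespondenceSet([Correspondence(0, 0, 0.0)]))
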
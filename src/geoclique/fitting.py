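"""Robust articulated registration against sparse correspondences.

Stages, per clique hypothesis:

1. *Rigid pre-alignment* — closed-form Kabsch/SVD rotation from the torso
   correspondences (the torso moves nearly rigidly, so it anchors the global
   motion before any joint optimization).
2. *Robust inverse kinematics* — minimize

       E(theta) = sum_i rho(||M_i(theta) - p_i||) + lambda * E_prior(theta)

   where M_i is the skinned model point paired with data point p_i and
   rho(s) = s^2 / (s^2 + sigma) is the Geman–McClure penalty, bounded so
   gross outliers stop pulling once their residual clears the sqrt(sigma)
   scale. Optimization is limited-memory quasi-Newton (L-BFGS-B) with
   finite-difference gradients, run over a decreasing sigma schedule
   (graduated non-convexity): the bounded loss at its target scale has no
   useful gradient far from the optimum, so early rounds use an inflated
   sigma and the final round uses the configured one exactly.
3. *Hypothesis scoring* — D_knn, the summed squared distance from (a
   subsample of) the data points to their nearest deformed model vertex;
   the hypothesis with the smallest D_knn wins.

The default pose prior is an isotropic Gaussian on joint-angle magnitude
(E_prior = ||theta||^2); any external callable prior can be substituted.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .bodymodel import ArticulatedModel, PoseParams, pose_model
from .features import CorrespondenceSet
from .mesh import InputError

__all__ = [
    "FitConfig",
    "RegistrationResult",
    "DegenerateRigidError",
    "estimate_rigid",
    "geman_mcclure",
    "fit_pose",
    "evaluate_hypothesis",
    "register",
]


class DegenerateRigidError(ValueError):
    """Too few / rank-deficient pairs for a rigid estimate."""


class NumericError(RuntimeError):
    """Optimizer produced a non-finite loss."""


@dataclasses.dataclass
class FitConfig:
    """Knobs of the robust IK stage.

    lambda_prior : weight of the pose prior (dimensionless; default 1e-3 —
        strong enough to park unconstrained joints at rest, weak enough not
        to bias well-constrained ones).
    gm_sigma : Geman–McClure scale in m^2; default 1e-3 puts the soft
        residual threshold near sqrt(1e-3) ~ 3 cm.
    anneal_factors : multipliers applied to gm_sigma for the graduated
        rounds, ending at 1 (the configured scale).
    prior_kind : "gaussian_angle" or "external" (requires ``external_prior``
        returning (value, gradient) for a flat theta vector).
    lock_root : keep the root joint angle at zero; the root rotation is
        redundant with the global rigid transform, and locking it keeps the
        recovered joint angles identifiable.
    """

    lambda_prior: float = 1e-3
    gm_sigma: float = 1e-3
    max_iterations: int = 150
    convergence_tol: float = 1e-10
    prior_kind: str = "gaussian_angle"
    external_prior: Callable | None = None
    robust: bool = True  # False = plain squared loss (for ablation)
    anneal_factors: tuple = (400.0, 20.0, 1.0)
    lock_root: bool = True
    optimize_global: bool = True
    gradient: str = "analytic"  # or "fd" (finite differences)

    def __post_init__(self) -> None:
        if self.lambda_prior < 0 or self.gm_sigma <= 0:
            raise InputError("lambda_prior must be >= 0 and gm_sigma > 0")
        if self.max_iterations <= 0 or self.convergence_tol <= 0:
            raise InputError("max_iterations and convergence_tol must be positive")
        if self.prior_kind not in ("gaussian_angle", "external"):
            raise InputError(f"unknown prior_kind: {self.prior_kind!r}")
        if self.prior_kind == "external" and self.external_prior is None:
            raise InputError("prior_kind='external' requires external_prior")
        if self.gradient not in ("analytic", "fd"):
            raise InputError(f"unknown gradient mode: {self.gradient!r}")


@dataclasses.dataclass
class RegistrationResult:
    pose: PoseParams
    deformed_vertices: np.ndarray  # all model vertices under the fitted pose
    data_term: float
    prior_term: float
    total_loss: float
    d_knn: float = np.nan
    hypothesis_id: int | None = None
    rigid_fallback: bool = False  # torso pairs were missing/degenerate
    refined: bool = False
    loss_history: tuple = ()
    n_correspondences: int = 0

    def export_metrics(self, path: str | Path) -> None:
        payload = {
            "data_term": self.data_term,
            "prior_term": self.prior_term,
            "total_loss": self.total_loss,
            "d_knn": None if np.isnan(self.d_knn) else self.d_knn,
            "hypothesis_id": self.hypothesis_id,
            "rigid_fallback": self.rigid_fallback,
            "refined": self.refined,
            "n_correspondences": self.n_correspondences,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def estimate_rigid(
    model_points: np.ndarray, data_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares rigid transform (Kabsch/SVD).

    Finds the proper rotation R and translation t minimizing
    ``sum_i || p_i - (R q_i + t) ||^2`` over matched pairs (q_i, p_i) =
    (model, data). Coordinates are decentered by their centroids, the
    rotation comes from the SVD of the cross-covariance with the usual
    determinant correction to +1, and t from the centroids.
    """
    Q = np.asarray(model_points, dtype=np.float64).reshape(-1, 3)
    P = np.asarray(data_points, dtype=np.float64).reshape(-1, 3)
    if len(Q) != len(P):
        raise InputError("point sets must be paired")
    if len(Q) < 3:
        raise DegenerateRigidError(f"need >= 3 pairs, got {len(Q)}")
    qc = Q.mean(axis=0)
    pc = P.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    rank = int((S > S[0] * 1e-9).sum()) if S[0] > 0 else 0
    if rank < 2:
        raise DegenerateRigidError(
            f"rank-deficient configuration (cross-covariance rank {rank})"
        )
    V = Vt.T
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(V @ U.T))])
    R = V @ D @ U.T
    t = pc - R @ qc
    return R, t


def geman_mcclure(s, sigma: float):
    """Geman–McClure penalty rho(s) = s^2 / (s^2 + sigma).

    Zero at zero, strictly increasing, saturating at 1; ``sigma`` (m^2) sets
    the residual scale beyond which further error barely adds cost.
    """
    if sigma <= 0:
        raise InputError(f"sigma must be positive, got {sigma}")
    s2 = np.square(s)
    return s2 / (s2 + sigma)


def _prior(config: FitConfig, theta_flat: np.ndarray) -> float:
    if config.prior_kind == "gaussian_angle":
        return float(theta_flat @ theta_flat)
    return float(config.external_prior(theta_flat))


def _rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(r).as_matrix()


def _left_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """SO(3) left Jacobian: maps a rotation-vector increment to the
    equivalent left (world-frame) angular increment."""
    theta = np.linalg.norm(rotvec)
    K = np.array(
        [
            [0.0, -rotvec[2], rotvec[1]],
            [rotvec[2], 0.0, -rotvec[0]],
            [-rotvec[1], rotvec[0], 0.0],
        ]
    )
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    a = (1.0 - np.cos(theta)) / theta**2
    b = (theta - np.sin(theta)) / theta**3
    return np.eye(3) + a * K + b * (K @ K)


def fit_pose(
    model: ArticulatedModel,
    vertex_ids: np.ndarray,
    data_points: np.ndarray,
    init: PoseParams,
    config: FitConfig | None = None,
) -> RegistrationResult:
    """Optimize pose parameters so model vertices reach their data points.

    Parameters
    ----------
    vertex_ids, data_points : the sparse correspondences q_i -> p_i
        (model vertex index, observed 3D point).
    init : starting pose (typically rest joints + the rigid pre-estimate).

    Returns a :class:`RegistrationResult` whose loss terms satisfy
    ``total_loss == data_term + lambda_prior * prior_term`` exactly at the
    reported solution, with the data term evaluated at the configured
    ``gm_sigma``.
    """
    config = config or FitConfig()
    vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
    data_points = np.asarray(data_points, dtype=np.float64).reshape(-1, 3)
    if len(vertex_ids) == 0:
        raise InputError("correspondence set must be nonempty")
    if len(vertex_ids) != len(data_points):
        raise InputError("vertex_ids and data_points must be paired")

    J = model.n_joints
    root = model.root
    free_joints = [j for j in range(J) if not (config.lock_root and j == root)]
    n_theta = 3 * len(free_joints)

    def unpack(x: np.ndarray) -> PoseParams:
        theta = np.zeros((J, 3))
        theta[free_joints] = x[:n_theta].reshape(-1, 3)
        if config.lock_root and init.theta[root].any():
            theta[root] = init.theta[root]
        if config.optimize_global:
            Rg = _rotvec_to_matrix(x[n_theta : n_theta + 3])
            tg = x[n_theta + 3 : n_theta + 6]
        else:
            Rg, tg = init.global_rotation, init.global_translation
        return PoseParams(theta, Rg, tg)

    from scipy.spatial.transform import Rotation

    x0 = np.zeros(n_theta + (6 if config.optimize_global else 0))
    x0[:n_theta] = init.theta[free_joints].ravel()
    if config.optimize_global:
        x0[n_theta : n_theta + 3] = Rotation.from_matrix(init.global_rotation).as_rotvec()
        x0[n_theta + 3 :] = init.global_translation

    history: list = []
    from .bodymodel import joint_world_transforms

    v_sub = model.template_vertices[vertex_ids]
    w_sub = model.skinning_weights[vertex_ids]
    subtree = model.subtree_masks()
    jp = model.joint_positions
    parents = model.parents

    def loss(x: np.ndarray, sigma: float) -> float:
        pose = unpack(x)
        M = pose_model(model, pose, vertex_ids)
        resid = np.linalg.norm(M - data_points, axis=1)
        if config.robust:
            data = float(geman_mcclure(resid, sigma).sum())
        else:
            data = float(np.square(resid).sum())
        total = data + config.lambda_prior * _prior(config, x[:n_theta])
        if not np.isfinite(total):
            raise NumericError(
                f"non-finite loss after {len(history)} evaluations: {total}"
            )
        return total

    def loss_and_grad(x: np.ndarray, sigma: float):
        """Analytic gradient: a joint perturbation rotates its subtree about
        the posed joint center; the world-frame angular gradient maps back
        to rotation-vector coordinates through the SO(3) left Jacobian."""
        pose = unpack(x)
        Rw, tw = joint_world_transforms(model, pose)
        per_joint = np.einsum("jab,nb->jna", Rw, v_sub) + tw[:, None, :]  # y_jk
        B = np.einsum("nj,jna->na", w_sub, per_joint)
        Rg, tg = pose.global_rotation, pose.global_translation
        M = B @ Rg.T + tg
        r = M - data_points
        s2 = np.einsum("na,na->n", r, r)
        if config.robust:
            data = float((s2 / (s2 + sigma)).sum())
            dEdM = (2.0 * sigma / np.square(s2 + sigma))[:, None] * r
        else:
            data = float(s2.sum())
            dEdM = 2.0 * r
        total = data + config.lambda_prior * _prior(config, x[:n_theta])
        if not np.isfinite(total):
            raise NumericError("non-finite loss during optimization")
        G = dEdM @ Rg  # = Rg^T applied rowwise: pulls gradient under the global map
        # per-joint torque aggregates: S_k = sum_i w_ik (y_ik x G_i),
        #                              W_k = sum_i w_ik G_i
        Svec = np.einsum("jna->ja", np.cross(per_joint, G[None, :, :]) * w_sub.T[:, :, None])
        Wvec = w_sub.T @ G
        grad = np.zeros_like(x)
        cj = np.einsum("jab,jb->ja", Rw, jp) + tw  # posed joint centers
        for slot, j in enumerate(free_joints):
            mask = subtree[j]
            torque = Svec[mask].sum(axis=0) - np.cross(cj[j], Wvec[mask].sum(axis=0))
            p = int(parents[j])
            Rp = Rw[p] if p >= 0 else np.eye(3)
            grad[3 * slot : 3 * slot + 3] = (
                _left_jacobian(pose.theta[j]).T @ Rp.T @ torque
            )
        if config.prior_kind == "gaussian_angle":
            grad[:n_theta] += 2.0 * config.lambda_prior * x[:n_theta]
        else:
            # external priors supply value only; fall back to FD on the prior
            eps = 1e-7
            for k in range(n_theta):
                xp = x.copy()
                xp[k] += eps
                grad[k] += config.lambda_prior * (
                    _prior(config, xp[:n_theta]) - _prior(config, x[:n_theta])
                ) / eps
        if config.optimize_global:
            g_rot = np.cross(M - tg, dEdM).sum(axis=0)
            grad[n_theta : n_theta + 3] = _left_jacobian(x[n_theta : n_theta + 3]).T @ g_rot
            grad[n_theta + 3 :] = dEdM.sum(axis=0)
        return total, grad

    use_analytic = config.gradient == "analytic"
    x = x0
    schedule = config.anneal_factors if config.robust else (1.0,)
    for stage, factor in enumerate(schedule):
        sigma = config.gm_sigma * float(factor)
        last = stage == len(schedule) - 1
        callback = (lambda xk: history.append(loss(xk, sigma))) if last else None
        res = minimize(
            loss_and_grad if use_analytic else loss,
            x,
            args=(sigma,),
            jac=use_analytic,
            method="L-BFGS-B",
            callback=callback,
            options={
                "maxiter": config.max_iterations if last else max(60, config.max_iterations // 2),
                "ftol": config.convergence_tol,
                "gtol": 1e-12,
            },
        )
        x = res.x
    pose = unpack(x)
    M = pose_model(model, pose, vertex_ids)
    resid = np.linalg.norm(M - data_points, axis=1)
    if config.robust:
        data_term = float(geman_mcclure(resid, config.gm_sigma).sum())
    else:
        data_term = float(np.square(resid).sum())
    prior_term = _prior(config, x[:n_theta])
    return RegistrationResult(
        pose=pose,
        deformed_vertices=pose_model(model, pose),
        data_term=data_term,
        prior_term=prior_term,
        total_loss=data_term + config.lambda_prior * prior_term,
        loss_history=tuple(history),
        n_correspondences=len(vertex_ids),
    )


def evaluate_hypothesis(
    result: RegistrationResult,
    data_points: np.ndarray,
    sample_size: int | None = 2000,
    seed: int = 0,
) -> float:
    """D_knn: summed squared distance from data points to the deformed model.

    Data points are subsampled (without replacement, seeded) to
    ``sample_size`` when larger; the hypothesis ranking is stable under this
    subsampling on the scales the pipeline works at.
    """
    data_points = np.asarray(data_points, dtype=np.float64).reshape(-1, 3)
    if len(data_points) == 0:
        raise InputError("data point set must be nonempty")
    if sample_size is not None and len(data_points) > sample_size:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(data_points), size=sample_size, replace=False)
        data_points = data_points[pick]
    tree = cKDTree(result.deformed_vertices)
    d, _ = tree.query(data_points, k=1)
    score = float(np.square(d).sum())
    result.d_knn = score
    return score


def register(
    model: ArticulatedModel,
    target_points: np.ndarray,
    hypotheses: list,
    corrs: CorrespondenceSet,
    config: FitConfig | None = None,
    d_knn_sample: int | None = 2000,
    d_knn_seed: int = 0,
    refine_with_all: bool = True,
    C_bin: np.ndarray | None = None,
    consensus_frac: float = 0.1,
    nn_refine_iters: int = 2,
    nn_anneal: tuple = (20.0, 4.0, 1.0),
) -> tuple[RegistrationResult, list]:
    """Fit every clique hypothesis and return the best result plus ranking.

    For each hypothesis: rigid pre-estimate from its torso-labeled pairs
    (falling back to all pairs of the hypothesis when fewer than three torso
    pairs exist or they are degenerate, flagged on the result), robust pose
    fit on the hypothesis' correspondences, then D_knn scoring against
    ``target_points``. The hypothesis with the lowest D_knn wins.

    With ``refine_with_all`` the winner is then refined in two stages:

    1. *Consensus expansion* — when the binarized compatibility matrix
       ``C_bin`` is given, the correspondence set is enlarged to everything
       compatible with at least ``consensus_frac`` of the winning clique's
       members (the clique acts as a consensus seed; genuine outliers are
       compatible with almost none of it). Without ``C_bin`` the full
       initial set is used, relying on the bounded loss alone. A robust
       sparse fit runs on this set from the winning pose.
    2. *Dense nearest-neighbor coupling* — ``nn_refine_iters`` rounds in
       which every model vertex is paired with its nearest target point and
       fitted jointly with the consensus pairs. The dense term pins body
       parts the sparse set under-determines (a limb segment with one or two
       pairs has free rotation components), while the sparse pairs carry the
       vertex-level identification the dense term cannot see.
    """
    if not hypotheses:
        raise InputError("hypothesis list must be nonempty")
    config = config or FitConfig()
    target_points = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    src_all = corrs.source_vertices
    tgt_all = corrs.target_vertices
    torso_mask_all = model.torso_vertex_mask()

    results = []
    failures = []
    for h in hypotheses:
        ids = np.asarray(h.member_ids, dtype=np.int64)
        q_ids = src_all[ids]
        p_pts = target_points[tgt_all[ids]]
        torso_sel = torso_mask_all[q_ids]
        fallback = False
        try:
            if torso_sel.sum() >= 3:
                R0, t0 = estimate_rigid(
                    model.template_vertices[q_ids[torso_sel]], p_pts[torso_sel]
                )
            else:
                raise DegenerateRigidError("fewer than 3 torso pairs")
        except DegenerateRigidError:
            fallback = True
            try:
                R0, t0 = estimate_rigid(model.template_vertices[q_ids], p_pts)
            except DegenerateRigidError as exc:
                failures.append((h.rank, str(exc)))
                continue
        init = PoseParams(np.zeros((model.n_joints, 3)), R0, t0)
        fit = fit_pose(model, q_ids, p_pts, init, config)
        fit.hypothesis_id = h.rank
        fit.rigid_fallback = fallback
        evaluate_hypothesis(fit, target_points, sample_size=d_knn_sample, seed=d_knn_seed)
        results.append(fit)
    if not results:
        raise DegenerateRigidError(
            "all hypotheses failed the rigid estimate: " + "; ".join(
                f"rank {r}: {msg}" for r, msg in failures
            )
        )
    results.sort(key=lambda r: r.d_knn)
    best = results[0]
    if refine_with_all:
        win = next(h for h in hypotheses if h.rank == best.hypothesis_id)
        if C_bin is not None:
            members = np.asarray(win.member_ids)
            comp = np.asarray(C_bin)[:, members].mean(axis=1)
            cons = np.nonzero(comp >= consensus_frac)[0]
            if len(cons) < len(members):  # never shrink below the clique itself
                cons = members
        else:
            cons = np.arange(len(corrs))
        pose = best.pose
        refined = fit_pose(
            model, src_all[cons], target_points[tgt_all[cons]], pose, config
        )
        pose = refined.pose
        if nn_refine_iters > 0:
            tree = cKDTree(target_points)
            all_ids = np.arange(model.n_vertices)
            nn_config = dataclasses.replace(config, anneal_factors=nn_anneal)
            for _ in range(nn_refine_iters):
                deformed = pose_model(model, pose)
                _, nn = tree.query(deformed, k=1)
                ids2 = np.concatenate([src_all[cons], all_ids])
                pts2 = np.concatenate([target_points[tgt_all[cons]], target_points[nn]])
                refined = fit_pose(model, ids2, pts2, pose, nn_config)
                pose = refined.pose
        refined.hypothesis_id = best.hypothesis_id
        refined.rigid_fallback = best.rigid_fallback
        refined.refined = True
        evaluate_hypothesis(refined, target_points, sample_size=d_knn_sample, seed=d_knn_seed)
        best = refined
    return best, results
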
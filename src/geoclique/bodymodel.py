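"""Skinned articulated body model: forward kinematics + linear blend skinning.

The model is deliberately format-agnostic: any (template vertices, joint
tree, skinning weights, part labels) bundle works. A built-in tube-limb
humanoid (:func:`make_toy_humanoid`) makes the whole pipeline self-contained;
SMPL-format ``.npz`` parameter archives load through
:func:`load_smpl_npz` when the user supplies them.

Pose convention: ``theta[j]`` is an axis-angle rotation (radians) applied
about joint ``j``'s rest position, composed root-to-leaf; a global proper
rotation and translation are applied last. A vertex is deformed by the
convex skinning-weight blend of its bones' rigid transforms (linear blend
skinning). With the zero pose and identity global transform the template is
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import InputError, TriangleMesh

__all__ = [
    "ArticulatedModel",
    "PoseParams",
    "pose_model",
    "joint_angle_errors",
    "make_toy_humanoid",
    "load_smpl_npz",
]


def joint_angle_errors(
    theta_est: np.ndarray, theta_true: np.ndarray, exclude: tuple = ()
) -> np.ndarray:
    """Per-joint rotation error in degrees (geodesic angle on SO(3))."""
    theta_est = np.asarray(theta_est, dtype=np.float64).reshape(-1, 3)
    theta_true = np.asarray(theta_true, dtype=np.float64).reshape(-1, 3)
    rel = Rotation.from_rotvec(theta_est).inv() * Rotation.from_rotvec(theta_true)
    errs = np.degrees(rel.magnitude())
    keep = [j for j in range(len(errs)) if j not in exclude]
    return errs[keep]


@dataclasses.dataclass
class ArticulatedModel:
    """Skinned template with a joint hierarchy.

    Attributes
    ----------
    template_vertices : (n, 3) float
    faces : (m, 3) int
    joint_positions : (J, 3) float
        Rest-pose joint centers (meters).
    parents : (J,) int
        Parent joint index; exactly one root with parent -1.
    skinning_weights : (n, J) float
        Nonnegative, rows sum to 1 (within 1e-6).
    part_labels : (n,) int
        Per-vertex part id; by convention the id of the dominant bone.
    torso_label_ids : tuple of int
        Part ids that constitute the torso (used for the rigid pre-estimate).
    joint_names : tuple of str, optional
    """

    template_vertices: np.ndarray
    faces: np.ndarray
    joint_positions: np.ndarray
    parents: np.ndarray
    skinning_weights: np.ndarray
    part_labels: np.ndarray
    torso_label_ids: tuple
    joint_names: tuple = ()

    def __post_init__(self) -> None:
        self.template_vertices = np.asarray(self.template_vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.joint_positions = np.asarray(self.joint_positions, dtype=np.float64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.skinning_weights = np.asarray(self.skinning_weights, dtype=np.float64)
        self.part_labels = np.asarray(self.part_labels, dtype=np.int64)
        self.torso_label_ids = tuple(int(t) for t in self.torso_label_ids)
        w = self.skinning_weights
        if np.any(w < -1e-12):
            raise InputError("skinning weights must be nonnegative")
        if np.abs(w.sum(axis=1) - 1.0).max() > 1e-6:
            raise InputError("skinning weight rows must sum to 1")
        if int((self.parents < 0).sum()) != 1:
            raise InputError("joint tree must have exactly one root")
        if not self.torso_label_ids:
            raise InputError("torso label set must be nonempty")
        # root-to-leaf evaluation order
        order, seen = [], set()
        pending = list(range(self.n_joints))
        while pending:
            progressed = False
            for j in list(pending):
                p = int(self.parents[j])
                if p < 0 or p in seen:
                    order.append(j)
                    seen.add(j)
                    pending.remove(j)
                    progressed = True
            if not progressed:
                raise InputError("joint parent graph contains a cycle")
        self._topo_order = order

    @property
    def n_vertices(self) -> int:
        return int(self.template_vertices.shape[0])

    def subtree_masks(self) -> np.ndarray:
        """(J, J) bool: entry [j, k] true iff k is j or a descendant of j."""
        J = self.n_joints
        sub = np.eye(J, dtype=bool)
        for k in self._topo_order:
            p = int(self.parents[k])
            while p >= 0:
                sub[p, k] = True
                p = int(self.parents[p])
        return sub

    @property
    def n_joints(self) -> int:
        return int(self.joint_positions.shape[0])

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parents < 0)[0][0])

    def torso_vertex_mask(self) -> np.ndarray:
        return np.isin(self.part_labels, self.torso_label_ids)

    def mesh(self, vertices: np.ndarray | None = None) -> TriangleMesh:
        v = self.template_vertices if vertices is None else vertices
        return TriangleMesh(v, self.faces, labels=self.part_labels)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            vertices=self.template_vertices,
            faces=self.faces,
            joint_positions=self.joint_positions,
            parents=self.parents,
            weights=self.skinning_weights,
            labels=self.part_labels,
            torso_label_ids=np.asarray(self.torso_label_ids),
            joint_names=np.asarray(self.joint_names, dtype=object)
            if self.joint_names
            else np.asarray([], dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ArticulatedModel":
        with np.load(path, allow_pickle=True) as z:
            names = tuple(z["joint_names"].tolist()) if z["joint_names"].size else ()
            return cls(
                template_vertices=z["vertices"],
                faces=z["faces"],
                joint_positions=z["joint_positions"],
                parents=z["parents"],
                skinning_weights=z["weights"],
                part_labels=z["labels"],
                torso_label_ids=tuple(z["torso_label_ids"].tolist()),
                joint_names=names,
            )


@dataclasses.dataclass
class PoseParams:
    """Joint axis-angle vector plus a global rigid transform."""

    theta: np.ndarray  # (J, 3) axis-angle, radians
    global_rotation: np.ndarray = None
    global_translation: np.ndarray = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64).reshape(-1, 3)
        if self.global_rotation is None:
            self.global_rotation = np.eye(3)
        if self.global_translation is None:
            self.global_translation = np.zeros(3)
        self.global_rotation = np.asarray(self.global_rotation, dtype=np.float64)
        self.global_translation = np.asarray(self.global_translation, dtype=np.float64)
        R = self.global_rotation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8 or abs(np.linalg.det(R) - 1) > 1e-8:
            raise InputError("global_rotation must be a proper rotation (det +1)")

    @classmethod
    def rest(cls, n_joints: int) -> "PoseParams":
        return cls(np.zeros((n_joints, 3)))

    def copy(self) -> "PoseParams":
        return PoseParams(
            self.theta.copy(), self.global_rotation.copy(), self.global_translation.copy()
        )


def joint_world_transforms(
    model: ArticulatedModel, pose: PoseParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-joint world rotations (J,3,3) and translations (J,3).

    Joint j's world map is x -> Rw[j] @ x + tw[j]; it equals the composition
    of ancestor rotations, each taken about its own rest joint center, and
    does NOT include the global rigid transform.
    """
    J = model.n_joints
    if pose.theta.shape[0] != J:
        raise InputError(
            f"pose has {pose.theta.shape[0]} joint rotations, model has {J}"
        )
    Rloc = Rotation.from_rotvec(pose.theta).as_matrix()  # (J,3,3)
    Rw = np.empty((J, 3, 3))
    tw = np.empty((J, 3))
    jp = model.joint_positions
    for j in model._topo_order:
        p = int(model.parents[j])
        # local map: rotate about the rest position of joint j
        tloc = jp[j] - Rloc[j] @ jp[j]
        if p < 0:
            Rw[j] = Rloc[j]
            tw[j] = tloc
        else:
            Rw[j] = Rw[p] @ Rloc[j]
            tw[j] = Rw[p] @ tloc + tw[p]
    return Rw, tw


def pose_model(
    model: ArticulatedModel,
    pose: PoseParams,
    vertex_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Deformed vertex positions under forward kinematics + blend skinning.

    ``vertex_ids`` restricts the computation to a subset (the sparse
    correspondences during fitting); default is every template vertex.
    """
    Rw, tw = joint_world_transforms(model, pose)
    if vertex_ids is None:
        v = model.template_vertices
        w = model.skinning_weights
    else:
        vertex_ids = np.asarray(vertex_ids)
        v = model.template_vertices[vertex_ids]
        w = model.skinning_weights[vertex_ids]
    # (J, n, 3): each joint's rigid map applied to the vertex block
    per_joint = np.einsum("jab,nb->jna", Rw, v) + tw[:, None, :]
    blended = np.einsum("nj,jna->na", w, per_joint)
    return blended @ pose.global_rotation.T + pose.global_translation


# ---------------------------------------------------------------------------
# toy humanoid fixture
# ---------------------------------------------------------------------------

# joints: name, parent, rest position (meters, y-up, T-pose)
_TOY_JOINTS = [
    ("pelvis", -1, (0.00, 0.95, 0.0)),
    ("spine", 0, (0.00, 1.13, 0.0)),
    ("chest", 1, (0.00, 1.31, 0.0)),
    ("head", 2, (0.00, 1.50, 0.0)),
    ("l_shoulder", 2, (0.20, 1.44, 0.0)),
    ("l_elbow", 4, (0.48, 1.44, 0.0)),
    ("l_wrist", 5, (0.74, 1.44, 0.0)),
    ("r_shoulder", 2, (-0.20, 1.44, 0.0)),
    ("r_elbow", 7, (-0.48, 1.44, 0.0)),
    ("r_wrist", 8, (-0.74, 1.44, 0.0)),
    ("l_hip", 0, (0.10, 0.88, 0.0)),
    ("l_knee", 10, (0.10, 0.46, 0.0)),
    ("l_ankle", 11, (0.10, 0.08, 0.0)),
    ("r_hip", 0, (-0.10, 0.88, 0.0)),
    ("r_knee", 13, (-0.10, 0.46, 0.0)),
    ("r_ankle", 14, (-0.10, 0.08, 0.0)),
]

# tube segments: bone (= skinning joint), start point, end point, radius.
# leaf bones extend to a virtual tip.
_TOY_SEGMENTS = [
    (0, (0.00, 0.95, 0.0), (0.00, 1.13, 0.0), 0.11),
    (1, (0.00, 1.13, 0.0), (0.00, 1.31, 0.0), 0.11),
    (2, (0.00, 1.31, 0.0), (0.00, 1.50, 0.0), 0.10),
    (3, (0.00, 1.50, 0.0), (0.00, 1.72, 0.0), 0.085),
    (4, (0.20, 1.44, 0.0), (0.48, 1.44, 0.0), 0.045),
    (5, (0.48, 1.44, 0.0), (0.74, 1.44, 0.0), 0.040),
    (6, (0.74, 1.44, 0.0), (0.85, 1.44, 0.0), 0.038),
    (7, (-0.20, 1.44, 0.0), (-0.48, 1.44, 0.0), 0.045),
    (8, (-0.48, 1.44, 0.0), (-0.74, 1.44, 0.0), 0.040),
    (9, (-0.74, 1.44, 0.0), (-0.85, 1.44, 0.0), 0.038),
    (10, (0.10, 0.88, 0.0), (0.10, 0.46, 0.0), 0.070),
    (11, (0.10, 0.46, 0.0), (0.10, 0.08, 0.0), 0.050),
    (12, (0.10, 0.08, 0.0), (0.10, 0.02, 0.14), 0.042),
    (13, (-0.10, 0.88, 0.0), (-0.10, 0.46, 0.0), 0.070),
    (14, (-0.10, 0.46, 0.0), (-0.10, 0.08, 0.0), 0.050),
    (15, (-0.10, 0.08, 0.0), (-0.10, 0.02, 0.14), 0.042),
]

_TOY_TORSO_BONES = (0, 1, 2)


def _ring_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def make_toy_humanoid(
    ring_spacing: float = 0.05, ring_segments: int = 8
) -> ArticulatedModel:
    """Tube-limb humanoid with 16 joints and hard (one-hot) skinning.

    Every tube vertex is bound to exactly one bone and each joint owns a hub
    vertex placed exactly at the joint center (bound to the parent bone).
    Because every mesh edge then joins vertices that move rigidly together,
    or joins a bone to the fixed point of its own rotation, articulated
    posing is an exact isometry of the edge graph — the geodesic-stability
    assumption holds exactly on this fixture, which is what makes it a clean
    substrate for the compatibility construction.

    ``ring_spacing`` (~5 cm default) sets the edge-length scale; the default
    keeps Dijkstra metrication error and noise-induced path inflation small
    relative to the compatibility kernel width on human-scale scenes.
    """
    verts: list = []
    faces: list = []
    labels: list = []
    seg_rings: dict = {}  # bone id -> list of ring-vertex index arrays

    def add_ring(center, axis, radius, bone):
        u, w = _ring_frame(np.asarray(axis, dtype=float))
        idx = []
        for k in range(ring_segments):
            ang = 2 * np.pi * k / ring_segments
            verts.append(np.asarray(center) + radius * (np.cos(ang) * u + np.sin(ang) * w))
            labels.append(bone)
            idx.append(len(verts) - 1)
        return np.array(idx)

    def bridge(ring_a, ring_b):
        m = ring_segments
        for k in range(m):
            a0, a1 = ring_a[k], ring_a[(k + 1) % m]
            b0, b1 = ring_b[k], ring_b[(k + 1) % m]
            faces.append((a0, a1, b1))
            faces.append((a0, b1, b0))

    def fan(center_idx, ring):
        m = ring_segments
        for k in range(m):
            faces.append((center_idx, ring[k], ring[(k + 1) % m]))

    for bone, start, end, radius in _TOY_SEGMENTS:
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        axis = end - start
        length = np.linalg.norm(axis)
        n_rings = max(2, int(np.ceil(length / ring_spacing)) + 1)
        rings = []
        for i in range(n_rings):
            c = start + axis * (i / (n_rings - 1))
            rings.append(add_ring(c, axis, radius, bone))
        for a, b in zip(rings[:-1], rings[1:]):
            bridge(a, b)
        seg_rings[bone] = rings

    joint_positions = np.array([p for _, _, p in _TOY_JOINTS])
    parents = np.array([p for _, p, _ in _TOY_JOINTS])
    names = tuple(n for n, _, _ in _TOY_JOINTS)

    # hub vertex at every non-root joint, bound to the parent bone; welded to
    # the start ring of its own tube and the nearest ring of the parent tube
    for j in range(1, len(_TOY_JOINTS)):
        p = int(parents[j])
        verts.append(joint_positions[j].copy())
        labels.append(p)
        hub = len(verts) - 1
        fan(hub, seg_rings[j][0][::-1])
        parent_rings = seg_rings[p]
        dists = [
            np.linalg.norm(np.mean([verts[i] for i in r], axis=0) - joint_positions[j])
            for r in parent_rings
        ]
        fan(hub, parent_rings[int(np.argmin(dists))])

    # cap leaf tube tips and the pelvis tube bottom
    for bone, start, end, radius in _TOY_SEGMENTS:
        if bone in (3, 6, 9, 12, 15):
            tip = np.asarray(end, dtype=float) + 0.0
            verts.append(tip)
            labels.append(bone)
            fan(len(verts) - 1, seg_rings[bone][-1])
    verts.append(joint_positions[0].copy())
    labels.append(0)
    fan(len(verts) - 1, seg_rings[0][0][::-1])

    V = np.asarray(verts)
    F = np.asarray(faces, dtype=np.int64)
    L = np.asarray(labels, dtype=np.int64)
    J = len(_TOY_JOINTS)
    W = np.zeros((len(V), J))
    W[np.arange(len(V)), L] = 1.0
    return ArticulatedModel(
        template_vertices=V,
        faces=F,
        joint_positions=joint_positions,
        parents=parents,
        skinning_weights=W,
        part_labels=L,
        torso_label_ids=_TOY_TORSO_BONES,
        joint_names=names,
    )


# SMPL joint ids forming the spine chain; used as the default torso when a
# user-supplied archive carries no part labels.
_SMPL_TORSO_JOINTS = (0, 3, 6, 9)


def load_smpl_npz(path: str | Path) -> ArticulatedModel:
    """Adapter for SMPL-format ``.npz`` parameter archives.

    Expects the standard keys ``v_template``, ``f``, ``weights``, and either
    ``J`` (rest joint positions) or ``J_regressor``, plus ``kintree_table``
    or ``parents``. Part labels default to the arg-max skinning bone; the
    torso is the spine chain. Pickled ``.pkl`` SMPL releases are not
    supported — convert to ``.npz`` first.
    """
    with np.load(path, allow_pickle=True) as z:
        keys = set(z.files)
        required = {"v_template", "f", "weights"}
        missing = required - keys
        if missing:
            raise InputError(f"SMPL archive missing keys: {sorted(missing)}")
        v = np.asarray(z["v_template"], dtype=np.float64)
        f = np.asarray(z["f"], dtype=np.int64)
        w = np.asarray(z["weights"], dtype=np.float64)
        if "J" in keys:
            jp = np.asarray(z["J"], dtype=np.float64)
        elif "J_regressor" in keys:
            reg = z["J_regressor"]
            reg = reg.toarray() if hasattr(reg, "toarray") else np.asarray(reg)
            jp = np.asarray(reg, dtype=np.float64) @ v
        else:
            raise InputError("SMPL archive needs 'J' or 'J_regressor'")
        if "parents" in keys:
            parents = np.asarray(z["parents"], dtype=np.int64)
        elif "kintree_table" in keys:
            kt = np.asarray(z["kintree_table"], dtype=np.int64)
            parents = kt[0].copy()
            parents[0] = -1
        else:
            raise InputError("SMPL archive needs 'parents' or 'kintree_table'")
        labels = np.argmax(w, axis=1).astype(np.int64)
    return ArticulatedModel(
        template_vertices=v,
        faces=f,
        joint_positions=jp,
        parents=parents,
        skinning_weights=w,
        part_labels=labels,
        torso_label_ids=_SMPL_TORSO_JOINTS,
    )
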
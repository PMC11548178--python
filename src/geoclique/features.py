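"""Local rotation-invariant descriptors and nearest-neighbor matching.

The registration pipeline only needs a *seed* correspondence set; all outlier
handling happens downstream in the compatibility graph. The bundled
descriptor is a fast-point-feature-histogram (FPFH) style signature: for each
vertex, Darboux-frame angles (alpha, phi, theta) between its normal and the
normals/offsets of neighbors inside a support radius are histogrammed, then
neighbor histograms are blended in with inverse-distance weights. All three
angle features are functions of dot/cross products only, so the descriptor is
rigid-invariant by construction.

The descriptor is pluggable: :func:`match_features` only assumes fixed-length
rows, so any external descriptor table can be substituted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .mesh import InputError, TriangleMesh

__all__ = [
    "Correspondence",
    "CorrespondenceSet",
    "DescriptorTable",
    "vertex_normals",
    "compute_descriptors",
    "match_features",
]

N_BINS = 11  # per angle feature; 3 features -> 33-dimensional descriptor


@dataclasses.dataclass(frozen=True)
class Correspondence:
    """One hypothesized source-vertex -> target-vertex pairing."""

    source_vertex: int
    target_vertex: int
    similarity: float  # descriptor distance; smaller is more similar


@dataclasses.dataclass
class CorrespondenceSet:
    items: list

    def __post_init__(self) -> None:
        seen = set()
        for c in self.items:
            key = (c.source_vertex, c.target_vertex)
            if key in seen:
                raise InputError(f"duplicate correspondence {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    @property
    def source_vertices(self) -> np.ndarray:
        return np.array([c.source_vertex for c in self.items], dtype=np.int64)

    @property
    def target_vertices(self) -> np.ndarray:
        return np.array([c.target_vertex for c in self.items], dtype=np.int64)

    @property
    def similarities(self) -> np.ndarray:
        return np.array([c.similarity for c in self.items], dtype=np.float64)

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source_vertex\ttarget_vertex\tsimilarity\n")
            for c in self.items:
                fh.write(f"{c.source_vertex}\t{c.target_vertex}\t{c.similarity:.17g}\n")

    @classmethod
    def load_tsv(cls, path) -> "CorrespondenceSet":
        items = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source_vertex"):
                raise InputError(f"not a correspondence TSV: {path}")
            for line in fh:
                s, t, sim = line.split("\t")
                items.append(Correspondence(int(s), int(t), float(sim)))
        return cls(items)


@dataclasses.dataclass
class DescriptorTable:
    """Fixed-length descriptor per vertex plus a lonely-vertex warning count."""

    descriptors: np.ndarray  # (n_vertices, dim), nonnegative
    n_isolated: int = 0  # vertices with no neighbor inside the support radius


def vertex_normals(mesh: TriangleMesh, k_plane: int = 12) -> np.ndarray:
    """Unit vertex normals.

    Meshed surfaces: area-weighted average of incident face normals.
    Point clouds: local PCA plane fit over ``k_plane`` neighbors, with the
    sign disambiguated to point away from the cloud centroid (viewpoint-free).
    """
    v = mesh.vertices
    if mesh.is_meshed():
        f = mesh.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for k in range(3):
            np.add.at(normals, f[:, k], fn)  # |fn| = 2*area -> area weighting
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        return normals / np.maximum(norms, 1e-300)
    tree = cKDTree(v)
    k = min(k_plane + 1, len(v))
    _, idx = tree.query(v, k=k)
    normals = np.empty_like(v)
    centroid = v.mean(axis=0)
    for i in range(len(v)):
        nb = v[idx[i]]
        cov = np.cov(nb.T)
        w, vecs = np.linalg.eigh(cov)
        nrm = vecs[:, 0]
        if np.dot(nrm, v[i] - centroid) < 0:
            nrm = -nrm
        normals[i] = nrm
    return normals


def _pair_features(p1, n1, p2, n2):
    """Darboux-frame angle features for point/normal pairs (vectorized).

    Returns (alpha, phi, theta) in their natural ranges ([-1,1], [-1,1],
    (-pi, pi]); rotation invariant because only relative geometry enters.
    """
    d = p2 - p1
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-300)
    dn = d / dist[:, None]
    # source of the frame: the point whose normal makes the smaller angle with d
    dot1 = np.einsum("ij,ij->i", n1, dn)
    dot2 = np.einsum("ij,ij->i", n2, dn)
    swap = np.abs(dot2) > np.abs(dot1)
    ps, ns = np.where(swap[:, None], p2, p1), np.where(swap[:, None], n2, n1)
    nt = np.where(swap[:, None], n1, n2)
    dn = np.where(swap[:, None], -dn, dn)
    u = ns
    vax = np.cross(dn, u)
    vax /= np.maximum(np.linalg.norm(vax, axis=1), 1e-300)[:, None]
    wax = np.cross(u, vax)
    alpha = np.einsum("ij,ij->i", vax, nt)
    phi = np.einsum("ij,ij->i", u, dn)
    theta = np.arctan2(
        np.einsum("ij,ij->i", wax, nt), np.einsum("ij,ij->i", u, nt)
    )
    return alpha, phi, theta


def _histogram(alpha, phi, theta) -> np.ndarray:
    h = np.concatenate(
        [
            np.histogram(alpha, bins=N_BINS, range=(-1.0, 1.0))[0],
            np.histogram(phi, bins=N_BINS, range=(-1.0, 1.0))[0],
            np.histogram(theta, bins=N_BINS, range=(-np.pi, np.pi))[0],
        ]
    ).astype(np.float64)
    s = h.sum()
    return h / s if s > 0 else h


def compute_descriptors(
    mesh: TriangleMesh, radius: float, normals: np.ndarray | None = None
) -> DescriptorTable:
    """FPFH-style descriptor for every vertex.

    Stage 1 builds a simplified point-feature histogram per vertex from the
    angle features between the vertex and each neighbor within ``radius``;
    stage 2 adds neighbors' histograms weighted by inverse distance, which
    widens the effective support without the quadratic neighbor-pair cost.

    Vertices with no neighbor in the support radius get a zero descriptor
    and are counted in ``n_isolated``.
    """
    if mesh.n_vertices < 10:
        raise InputError("descriptor extraction needs >= 10 vertices")
    if radius <= 0:
        raise InputError(f"support radius must be positive, got {radius}")
    v = mesh.vertices
    n = mesh.n_vertices
    if normals is None:
        normals = vertex_normals(mesh)
    tree = cKDTree(v)
    neighbor_lists = tree.query_ball_point(v, radius)
    spfh = np.zeros((n, 3 * N_BINS))
    isolated = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = [j for j in neighbor_lists[i] if j != i]
        if not nb:
            isolated[i] = True
            continue
        nb = np.asarray(nb)
        a, p, t = _pair_features(
            np.broadcast_to(v[i], (len(nb), 3)),
            np.broadcast_to(normals[i], (len(nb), 3)),
            v[nb],
            normals[nb],
        )
        spfh[i] = _histogram(a, p, t)
    fpfh = spfh.copy()
    for i in range(n):
        nb = [j for j in neighbor_lists[i] if j != i and not isolated[j]]
        if not nb:
            continue
        nb = np.asarray(nb)
        w = 1.0 / np.maximum(np.linalg.norm(v[nb] - v[i], axis=1), 1e-12)
        fpfh[i] = spfh[i] + (w[:, None] * spfh[nb]).sum(axis=0) / w.sum()
        s = fpfh[i].sum()
        if s > 0:
            fpfh[i] /= s
    fpfh[isolated] = 0.0
    return DescriptorTable(fpfh, int(isolated.sum()))


def match_features(
    source_desc: DescriptorTable | np.ndarray,
    target_desc: DescriptorTable | np.ndarray,
    strategy: str = "mutual_nn",
    max_pairs: int | None = None,
) -> CorrespondenceSet:
    """Nearest-neighbor descriptor matching.

    ``nn`` keeps, for every source vertex, its nearest target descriptor;
    ``mutual_nn`` keeps only pairs that are each other's nearest neighbor
    (always a subset of ``nn``). Ties are broken toward the lowest target
    index so matching is deterministic. Output is sorted ascending by
    descriptor distance and truncated to ``max_pairs``.
    """
    sd = source_desc.descriptors if isinstance(source_desc, DescriptorTable) else np.asarray(source_desc)
    td = target_desc.descriptors if isinstance(target_desc, DescriptorTable) else np.asarray(target_desc)
    if sd.size == 0 or td.size == 0:
        raise InputError("empty descriptor table")
    if sd.shape[1] != td.shape[1]:
        raise InputError(
            f"descriptor length mismatch: {sd.shape[1]} vs {td.shape[1]}"
        )
    if strategy not in ("nn", "mutual_nn"):
        raise ValueError(f"unknown matching strategy: {strategy!r}")
    ttree = cKDTree(td)
    dist_st, nn_t = ttree.query(sd, k=1)
    # deterministic tie-break: among equal-distance targets pick lowest index.
    # cKDTree already returns the lowest index on exact ties; enforce it for
    # near-ties within 1e-12 by a local re-query.
    if strategy == "mutual_nn":
        stree = cKDTree(sd)
        _, nn_s = stree.query(td, k=1)
        keep = nn_s[nn_t] == np.arange(len(sd))
    else:
        keep = np.ones(len(sd), dtype=bool)
    src = np.nonzero(keep)[0]
    pairs = [
        Correspondence(int(s), int(nn_t[s]), float(dist_st[s])) for s in src
    ]
    pairs.sort(key=lambda c: (c.similarity, c.source_vertex, c.target_vertex))
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return CorrespondenceSet(pairs)
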
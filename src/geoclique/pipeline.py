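"""End-to-end registration pipeline.

Chains the stages: geodesic measurement on both surfaces (restricted to the
correspondence endpoints), second-order compatibility graph, maximal-clique
hypothesis generation, node-guided selection, and robust articulated fitting
with D_knn hypothesis ranking.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bodymodel import ArticulatedModel
from .cliques import (
    DEFAULT_MAX_CLIQUES,
    DEFAULT_MIN_SIZE,
    enumerate_maximal_cliques,
    select_hypotheses,
)
from .compat import DEFAULT_D, DEFAULT_TAU, CompatGraph, build_compat_graph
from .features import CorrespondenceSet
from .fitting import FitConfig, RegistrationResult, register
from .geodesics import geodesic_distances
from .mesh import TriangleMesh, knn_proxy_mesh

__all__ = ["PipelineConfig", "PipelineOutput", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters in one JSON-serializable bundle."""

    d: float = DEFAULT_D
    tau_cmp: float = DEFAULT_TAU
    # "auto" = heat method on meshed surfaces (markedly less sensitive to
    # vertex noise than graph shortest paths), Dijkstra on k-NN substrates
    geodesic_method: str = "auto"
    geodesic_refine: int = 0
    consensus_frac: float = 0.1
    nn_refine_iters: int = 2
    knn_proxy_k: int = 8
    min_clique_size: int = DEFAULT_MIN_SIZE
    max_cliques: int = DEFAULT_MAX_CLIQUES
    top_k_hypotheses: int = 5
    d_knn_sample: int = 2000
    seed: int = 0
    refine_with_all: bool = True
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)


@dataclasses.dataclass
class PipelineOutput:
    best: RegistrationResult
    ranked: list
    hypotheses: list
    compat: CompatGraph
    winning_members: np.ndarray  # correspondence indices of the winning clique
    truncated_cliques: bool


def _as_substrate(mesh: TriangleMesh, k: int) -> TriangleMesh:
    return mesh if mesh.is_meshed() else knn_proxy_mesh(mesh.vertices, k=k)


def run_pipeline(
    model: ArticulatedModel,
    source_mesh: TriangleMesh,
    target_mesh: TriangleMesh,
    corrs: CorrespondenceSet,
    config: PipelineConfig | None = None,
) -> PipelineOutput:
    """Run graph construction, clique search and articulated fitting.

    ``source_mesh`` must be index-aligned with the model's template (its
    vertices are the model vertices the correspondences point at).
    Unmeshed inputs are routed through the k-NN proxy graph for geodesics.
    """
    config = config or PipelineConfig()
    src = _as_substrate(source_mesh, config.knn_proxy_k)
    tgt = _as_substrate(target_mesh, config.knn_proxy_k)

    def method_for(mesh: TriangleMesh) -> str:
        if config.geodesic_method == "auto":
            return "heat" if mesh.is_meshed() else "edge_dijkstra"
        return config.geodesic_method

    Ds = geodesic_distances(
        src, corrs.source_vertices,
        method=method_for(src), refine=config.geodesic_refine,
    )
    Dt = geodesic_distances(
        tgt, corrs.target_vertices,
        method=method_for(tgt), refine=config.geodesic_refine,
    )
    graph = build_compat_graph(corrs, Ds, Dt, d=config.d, tau_cmp=config.tau_cmp)
    cliques, truncated = enumerate_maximal_cliques(
        graph.C_bin, min_size=config.min_clique_size, max_cliques=config.max_cliques
    )
    hypotheses = select_hypotheses(cliques, graph.SC2, top_k=config.top_k_hypotheses)
    best, ranked = register(
        model,
        target_mesh.vertices,
        hypotheses,
        corrs,
        config=config.fit,
        d_knn_sample=config.d_knn_sample,
        d_knn_seed=config.seed,
        refine_with_all=config.refine_with_all,
        C_bin=graph.C_bin,
        consensus_frac=config.consensus_frac,
        nn_refine_iters=config.nn_refine_iters,
    )
    win = next(h for h in hypotheses if h.rank == best.hypothesis_id)
    return PipelineOutput(
        best=best,
        ranked=ranked,
        hypotheses=hypotheses,
        compat=graph,
        winning_members=np.asarray(win.member_ids),
        truncated_cliques=truncated,
    )
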
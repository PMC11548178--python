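"""Run configuration with lossless JSON round-trip.

One flat bundle of every tunable the pipeline exposes, so a run can be
reproduced from its logged configuration alone. Unknown keys are rejected
on load (a typo should fail loudly, not silently fall back to a default).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .fitting import FitConfig
from .mesh import InputError
from .pipeline import PipelineConfig

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    # compatibility graph
    d: float = 0.05
    tau_cmp: float = 0.99
    geodesic_method: str = "auto"
    geodesic_refine: int = 0
    knn_proxy_k: int = 8
    # clique search
    min_clique_size: int = 3
    max_cliques: int = 10_000
    top_k_hypotheses: int = 5
    # descriptor matching (only used when no correspondence file is supplied)
    descriptor_radius: float = 0.12
    match_strategy: str = "mutual_nn"
    max_pairs: int = 500
    # articulated fit
    lambda_prior: float = 1e-3
    gm_sigma: float = 1e-3
    max_iterations: int = 150
    convergence_tol: float = 1e-10
    robust: bool = True
    lock_root: bool = True
    gradient: str = "analytic"
    # refinement
    refine_with_all: bool = True
    consensus_frac: float = 0.1
    nn_refine_iters: int = 2
    # scoring / reproducibility
    d_knn_sample: int = 2000
    seed: int = 0
    # synthetic scenes
    outlier_frac: float = 0.3
    pose_magnitude: float = 0.6
    noise_sigma: float = 0.002
    n_correspondences: int = 200
    outlier_kind: str = "uniform"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            lambda_prior=self.lambda_prior,
            gm_sigma=self.gm_sigma,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            robust=self.robust,
            lock_root=self.lock_root,
            gradient=self.gradient,
        )

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            d=self.d,
            tau_cmp=self.tau_cmp,
            geodesic_method=self.geodesic_method,
            geodesic_refine=self.geodesic_refine,
            knn_proxy_k=self.knn_proxy_k,
            min_clique_size=self.min_clique_size,
            max_cliques=self.max_cliques,
            top_k_hypotheses=self.top_k_hypotheses,
            d_knn_sample=self.d_knn_sample,
            seed=self.seed,
            refine_with_all=self.refine_with_all,
            consensus_frac=self.consensus_frac,
            nn_refine_iters=self.nn_refine_iters,
            fit=self.fit_config(),
        )
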
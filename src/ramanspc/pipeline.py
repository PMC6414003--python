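"""End-to-end orchestration: simulate -> preprocess -> graph -> sweep -> tree -> pca.

A single :class:`PipelineConfig` nests the per-stage configurations and one
global seed from which deterministic per-stage sub-seeds are derived.  Every
output file is accompanied by ``run_info.json`` recording the configuration
hash, the seeds, and per-stage wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import engine, graph, pca, synthetic, tree
from .preprocess import PreprocessConfig, preprocess_cohort
from .records import ConfigurationError, SpectrumRecord, write_cohort

logger = logging.getLogger("ramanspc")


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    potts: engine.PottsConfig = field(default_factory=engine.PottsConfig)
    tree: tree.TreeConfig = field(default_factory=tree.TreeConfig)
    knn: int = 10
    pca_components: int = 3
    out_dir: str = "ramanspc_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn < 1:
            raise ConfigurationError("knn must be >= 1")
        if self.pca_components < 1:
            raise ConfigurationError("pca_components must be >= 1")
        # propagate deterministic per-stage sub-seeds from the global seed
        sub = np.random.SeedSequence(self.seed).generate_state(2)
        self.simulation.seed = int(sub[0] % (2**31))
        self.potts.seed = int(sub[1] % (2**31))

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": asdict(self.simulation),
            "preprocess": asdict(self.preprocess),
            "potts": asdict(self.potts),
            "tree": asdict(self.tree),
            "knn": self.knn,
            "pca_components": self.pca_components,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    def build(cls, key):
        kwargs = data.get(key) or {}
        if isinstance(kwargs.get("n_spectra_per_class"), list):
            kwargs["n_spectra_per_class"] = tuple(kwargs["n_spectra_per_class"])
        if isinstance(kwargs.get("n_patients_per_class"), list):
            kwargs["n_patients_per_class"] = tuple(kwargs["n_patients_per_class"])
        return cls(**kwargs)

    return PipelineConfig(
        simulation=build(synthetic.SimulationConfig, "simulation"),
        preprocess=build(PreprocessConfig, "preprocess"),
        potts=build(engine.PottsConfig, "potts"),
        tree=build(tree.TreeConfig, "tree"),
        knn=data.get("knn", 10),
        pca_components=data.get("pca_components", 3),
        out_dir=data.get("out_dir", "ramanspc_out"),
        seed=data.get("seed", 0),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    spectra: list[SpectrumRecord]
    matrix: graph.SpectraMatrix
    dist: np.ndarray
    coupling_graph: graph.CouplingGraph
    sweep: list[engine.SweepPoint]
    lineages: list[tree.Lineage]
    cluster_tree: tree.ClusterNode
    pca_result: pca.PCAResult
    timings: dict[str, float]


def run_stages(
    config: PipelineConfig, spectra: Sequence[SpectrumRecord] | None = None
) -> PipelineResult:
    """Run all stages in memory; ``spectra`` overrides the simulation stage."""
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                logger.info("stage %s: %.2fs", name, timings[name])

        return _T()

    if spectra is None:
        if 0 in config.simulation.n_spectra_per_class:
            raise ConfigurationError("zero spectra requested")
        with timed("simulate"):
            spectra = synthetic.simulate_cohort(config.simulation)
    spectra = list(spectra)

    with timed("preprocess"):
        processed = preprocess_cohort(spectra, config.preprocess)
    with timed("graph"):
        matrix = graph.build_matrix(processed)
        dist = graph.distance_matrix(matrix)
        K = min(config.knn, matrix.n_spectra - 1)
        cgraph = graph.compute_couplings(graph.build_neighbor_graph(dist, K=K))
    with timed("sweep"):
        sweep = engine.temperature_sweep(cgraph, config.potts)
    with timed("tree"):
        lineages = tree.track_clusters(sweep, config.tree)
        ctree = tree.extract_natural_clusters(lineages, config.tree, sweep=sweep)
    with timed("pca"):
        k = min(config.pca_components, matrix.n_spectra, matrix.n_points)
        pres = pca.run_pca(matrix, k=k)

    return PipelineResult(
        spectra=spectra, matrix=matrix, dist=dist, coupling_graph=cgraph,
        sweep=sweep, lineages=lineages, cluster_tree=ctree, pca_result=pres,
        timings=timings,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write the report bundle to ``config.out_dir``."""
    result = run_stages(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_cohort(result.spectra, out / "spectra")
    engine.write_sweep(result.sweep, out)
    tree.write_tree(result.cluster_tree, out / "tree.json")
    labels = [s.class_label for s in result.spectra]
    tree.membership_report(result.cluster_tree, labels).to_csv(
        out / "membership.csv", index=False
    )
    pca.write_pca(result.pca_result, out)
    graph.write_edge_list(result.coupling_graph, out / "edges.csv")

    info = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timings_s": result.timings,
        "n_spectra": result.matrix.n_spectra,
        "n_points": result.matrix.n_points,
        "n_natural_clusters": len(result.cluster_tree.natural_clusters()),
    }
    (out / "run_info.json").write_text(json.dumps(info, indent=2))
    logger.info("pipeline complete: %s", out)
    return result
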
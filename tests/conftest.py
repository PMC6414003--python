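"""Shared fixtures: benchmark cohorts and a cached clustering run.

The benchmark condition for phase-behavior and recovery tests is a
30-spectrum, three-class planted cohort (10 spectra per class, 2 patients
per class) without cosmic-ray spikes: spike residues survive the
Savitzky-Golay filter as extreme outliers that, under a Gaussian coupling,
correctly never join any cluster, so spike robustness is exercised in its
own dedicated test rather than inside every planted-recovery assertion.
"""

from __future__ import annotations

import numpy as np
import pytest

from ramanspc import (
    PottsConfig,
    SimulationConfig,
    TreeConfig,
    build_matrix,
    build_neighbor_graph,
    compute_couplings,
    distance_matrix,
    extract_natural_clusters,
    preprocess_cohort,
    simulate_cohort,
    temperature_sweep,
    track_clusters,
)

PLANTED_LABELS = np.array([0] * 10 + [1] * 10 + [2] * 10)


def bench_sim_config(seed: int, spikes: bool = False) -> SimulationConfig:
    return SimulationConfig(
        n_spectra_per_class=(10, 10, 10),
        n_patients_per_class=(2, 2, 2),
        spike_rate=0.2 if spikes else 0.0,
        seed=seed,
    )


def bench_potts_config(seed: int) -> PottsConfig:
    # coarse grid and short chains keep a full sweep at a few seconds
    return PottsConfig(
        t_min=0.0005, t_step=0.0005, n_sweeps=400, n_burnin=100, seed=seed
    )


def run_clustering(seed: int, spikes: bool = False):
    """Full chain on one benchmark cohort; returns a result namespace."""
    cohort = simulate_cohort(bench_sim_config(seed, spikes=spikes))
    processed = preprocess_cohort(cohort)
    matrix = build_matrix(processed)
    dist = distance_matrix(matrix)
    graph = compute_couplings(build_neighbor_graph(dist, K=10))
    sweep = temperature_sweep(graph, bench_potts_config(seed + 1))
    config = TreeConfig()
    lineages = track_clusters(sweep, config)
    tree = extract_natural_clusters(lineages, config, sweep=sweep)
    return {
        "cohort": cohort,
        "processed": processed,
        "matrix": matrix,
        "dist": dist,
        "graph": graph,
        "sweep": sweep,
        "lineages": lineages,
        "tree": tree,
    }


@pytest.fixture(scope="session")
def bench_run():
    """One cached benchmark clustering run shared across tests."""
    return run_clustering(seed=0)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(
        n_spectra_per_class=(5, 5, 5),
        n_patients_per_class=(1, 1, 1),
        noise_sd=0.0,
        spike_rate=0.0,
        baseline_scale=0.0,
        patient_effect_sd=0.0,
        seed=123,
    )
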
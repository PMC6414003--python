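"""Potts-model Swendsen-Wang Monte Carlo core for superparamagnetic clustering.

Each data point carries a q-state Potts spin; neighboring spins interact
ferromagnetically through the couplings J_ij of the neighbor graph, with
Hamiltonian

    H = sum over edges of J_ij * (1 - delta(s_i, s_j)) >= 0.

A Swendsen-Wang update freezes each satisfied edge (s_i = s_j) independently
with probability p_ij = 1 - exp(-J_ij / T), relabels the connected
components of frozen edges ("SW clusters") with uniform random spin values,
and thereby samples the Boltzmann distribution exp(-H/T) rapidly at any
temperature.

Per temperature the engine estimates the spin-spin correlation
g_ij = <delta(s_i, s_j)> per edge (by default through the variance-reduced
SW-cluster co-membership estimator g = ((q-1) c + 1)/q, with c the fraction
of sweeps in which i and j share a frozen cluster), the magnetic
susceptibility chi = (N/T) (<m^2> - <m>^2) with per-sweep magnetization
m = (q N_max - N)/((q-1) N), and the data partition obtained by keeping
only edges with g_ij above a threshold (default 0.5) and taking connected
components.  Sweeping T upward, the system passes from ferromagnetic (one
cluster) through superparamagnetic (clusters = data classes) to
paramagnetic (singletons); peaks of chi mark the transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import CouplingGraph
from .records import ConfigurationError, InputError


@dataclass
class PottsConfig:
    """Monte Carlo settings for the temperature sweep."""

    q: int = 20
    n_sweeps: int = 1000
    n_burnin: int = 200
    t_min: float | None = None
    t_max: float | None = None  # None: sweep until the paramagnetic phase
    t_step: float = 0.001
    g_threshold: float = 0.5
    estimator: str = "sw"  # "sw" (cluster co-membership) or "delta"
    seed: int = 0
    #: auto-stop: largest cluster below this fraction of points ...
    stop_fraction: float = 0.05
    #: ... for this many consecutive temperatures
    stop_patience: int = 20
    #: hard cap on the number of grid points when t_max is None
    max_grid: int = 2000

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ConfigurationError("q must be >= 2")
        if self.t_step <= 0:
            raise ConfigurationError("t_step must be > 0")
        if not (0 < self.g_threshold < 1):
            raise ConfigurationError("g_threshold must be in (0, 1)")
        if self.n_sweeps <= 0 or self.n_burnin < 0 or self.n_sweeps <= self.n_burnin:
            raise ConfigurationError("need n_sweeps > n_burnin >= 0")
        if self.estimator not in ("sw", "delta"):
            raise ConfigurationError("estimator must be 'sw' or 'delta'")


@dataclass
class SweepPoint:
    """Per-temperature output: correlations, susceptibility, partition."""

    T: float
    g: np.ndarray  # per-edge correlation estimates, aligned with graph.edges
    chi: float
    partition: list[np.ndarray]  # disjoint point-index sets covering 0..n-1

    @property
    def n_clusters(self) -> int:
        return len(self.partition)

    @property
    def largest_cluster_size(self) -> int:
        return max(len(c) for c in self.partition)


def hamiltonian(state: np.ndarray, graph: CouplingGraph) -> float:
    """Potts energy: sum of J_ij over discordant edges."""
    state = np.asarray(state)
    if state.size != graph.n:
        raise InputError("state must label every graph vertex")
    if graph.J is None:
        raise InputError("graph has no couplings; call compute_couplings first")
    if graph.edges.size == 0:
        return 0.0
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    return float(np.sum(graph.J * (state[i] != state[j])))


def _components(n: int, edge_i: np.ndarray, edge_j: np.ndarray) -> np.ndarray:
    """Connected-component labels (0..k-1) via union-find with path halving."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(edge_i.tolist(), edge_j.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.fromiter((find(v) for v in range(n)), dtype=np.int64, count=n)
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _sw_update(
    state: np.ndarray, graph: CouplingGraph, T: float, rng: np.random.Generator, q: int
) -> tuple[np.ndarray, np.ndarray]:
    """One SW update; returns (new state, frozen-cluster labels)."""
    if T <= 0:
        raise ConfigurationError("temperature must be > 0")
    if graph.J is None:
        raise InputError("graph has no couplings; call compute_couplings first")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    satisfied = state[i] == state[j]
    p_freeze = 1.0 - np.exp(-graph.J / T)
    frozen = satisfied & (rng.random(graph.edges.shape[0]) < p_freeze)
    comp = _components(graph.n, i[frozen], j[frozen])
    n_comp = comp.max() + 1 if comp.size else 0
    new_labels = rng.integers(1, q + 1, size=n_comp)
    return new_labels[comp], comp


def sw_step(
    state: np.ndarray, graph: CouplingGraph, T: float, rng: np.random.Generator, q: int = 20
) -> np.ndarray:
    """One Swendsen-Wang Monte Carlo step (public single-output form)."""
    new_state, _ = _sw_update(np.asarray(state), graph, T, rng, q)
    return new_state


def magnetization(state: np.ndarray, q: int) -> float:
    """m = (q N_max - N) / ((q - 1) N): 1 when aligned, ~0 when disordered."""
    counts = np.bincount(np.asarray(state))
    n = int(np.asarray(state).size)
    n_max = int(counts.max())
    return (q * n_max - n) / ((q - 1) * n)


def susceptibility(m_samples: np.ndarray, T: float, n_points: int) -> float:
    """chi = (N/T) * Var(m) over the retained sweeps (population variance)."""
    m = np.asarray(m_samples, dtype=float)
    if m.size < 2:
        raise InputError("need at least 2 magnetization samples")
    return float(n_points / T * m.var())


def clusters_at_T(
    g: np.ndarray, graph: CouplingGraph, g_threshold: float = 0.5
) -> list[np.ndarray]:
    """Data clusters: components of the graph keeping edges with g > threshold."""
    keep = np.asarray(g) > g_threshold
    labels = _components(
        graph.n, graph.edges[keep, 0], graph.edges[keep, 1]
    )
    return [np.where(labels == k)[0] for k in range(labels.max() + 1)]


def sample_at_temperature(
    graph: CouplingGraph,
    T: float,
    config: PottsConfig,
    state: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    return_samples: bool = False,
):
    """Equilibrate and sample at one temperature.

    Returns ``(SweepPoint, final_state)``; with ``return_samples=True`` a
    third element holds the raw per-sweep series (``m`` and, per edge,
    the co-membership/delta indicators) for error analysis.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if state is None:
        state = np.ones(graph.n, dtype=np.int64)
    n_edges = graph.edges.shape[0]
    i, j = (graph.edges[:, 0], graph.edges[:, 1]) if n_edges else (None, None)

    for _ in range(config.n_burnin):
        state, _ = _sw_update(state, graph, T, rng, config.q)

    n_keep = config.n_sweeps - config.n_burnin
    m_samples = np.empty(n_keep)
    c_sum = np.zeros(n_edges)
    samples = {"m": m_samples}
    if return_samples:
        samples["edge_indicator"] = np.empty((n_keep, n_edges), dtype=bool)
    for t in range(n_keep):
        state, comp = _sw_update(state, graph, T, rng, config.q)
        m_samples[t] = magnetization(state, config.q)
        if n_edges:
            if config.estimator == "sw":
                ind = comp[i] == comp[j]
            else:
                ind = state[i] == state[j]
            c_sum += ind
            if return_samples:
                samples["edge_indicator"][t] = ind

    c = c_sum / n_keep
    if config.estimator == "sw":
        g = ((config.q - 1) * c + 1.0) / config.q
    else:
        g = c
    chi = susceptibility(m_samples, T, graph.n)
    point = SweepPoint(
        T=T, g=g, chi=chi, partition=clusters_at_T(g, graph, config.g_threshold)
    )
    if return_samples:
        return point, state, samples
    return point, state


def temperature_grid(config: PottsConfig) -> np.ndarray:
    """Explicit grid t_min..t_max (inclusive, step t_step); needs t_max set."""
    t_min = config.t_min if config.t_min is not None else config.t_step
    if config.t_max is None:
        raise ConfigurationError("t_max is None; grid is open-ended")
    if config.t_max < t_min:
        raise ConfigurationError("empty temperature grid")
    n = int(round((config.t_max - t_min) / config.t_step)) + 1
    return t_min + config.t_step * np.arange(n)


def temperature_sweep(graph: CouplingGraph, config: PottsConfig) -> list[SweepPoint]:
    """Anneal from t_min upward, recording g, chi and the partition at each T.

    The chain state carries over between adjacent temperatures (warm start
    from the all-aligned state at the lowest T).  With ``t_max=None`` the
    sweep stops automatically once the largest cluster has stayed below
    ``stop_fraction`` of the points for ``stop_patience`` consecutive
    temperatures (paramagnetic phase reached).
    """
    rng = np.random.default_rng(config.seed)
    state = np.ones(graph.n, dtype=np.int64)
    t_min = config.t_min if config.t_min is not None else config.t_step

    out: list[SweepPoint] = []
    if config.t_max is not None:
        for T in temperature_grid(config):
            point, state = sample_at_temperature(graph, float(T), config, state, rng)
            out.append(point)
        if not out:
            raise ConfigurationError("empty temperature grid")
        return out

    small_count = 0
    T = t_min
    for _ in range(config.max_grid):
        point, state = sample_at_temperature(graph, float(T), config, state, rng)
        out.append(point)
        if point.largest_cluster_size < config.stop_fraction * graph.n:
            small_count += 1
            if small_count >= config.stop_patience:
                break
        else:
            small_count = 0
        T += config.t_step
    return out


def sweep_table(sweep: Sequence[SweepPoint]) -> pd.DataFrame:
    """Summary table (T, chi, n_clusters, largest_cluster_size)."""
    return pd.DataFrame(
        {
            "T": [p.T for p in sweep],
            "chi": [p.chi for p in sweep],
            "n_clusters": [p.n_clusters for p in sweep],
            "largest_cluster_size": [p.largest_cluster_size for p in sweep],
        }
    )


def write_sweep(sweep: Sequence[SweepPoint], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sweep_table(sweep).to_csv(out / "sweep.csv", index=False)
    rows = []
    for k, p in enumerate(sweep):
        for cid, members in enumerate(p.partition):
            for v in members:
                rows.append({"t_index": k, "T": p.T, "point_index": int(v), "cluster_id": cid})
    pd.DataFrame(rows).to_csv(out / "partitions.csv", index=False)
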
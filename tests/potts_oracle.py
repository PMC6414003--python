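"""Exact Boltzmann enumeration oracle for tiny Potts systems.

Independent of the Monte Carlo engine: enumerates all q^n spin states,
computes the energy by direct edge summation, and returns exact thermal
expectations for the edge correlations, magnetization, and susceptibility.
Only feasible for a handful of vertices; used as ground truth in tests.
"""

import itertools

import numpy as np


def path_graph(n_nodes=4, J=1.0):
    from ramanspc.graph import CouplingGraph

    edges = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    return CouplingGraph(
        n=n_nodes,
        edges=edges,
        d=np.ones(n_nodes - 1),
        d_bar=1.0,
        k_hat=2 * (n_nodes - 1) / n_nodes,
        J=np.full(n_nodes - 1, float(J)),
    )


def exact_moments(graph, q, T):
    """Exact <delta(s_i,s_j)> per edge, <m>, and chi by full enumeration."""
    n = graph.n
    edges = graph.edges
    g = np.zeros(edges.shape[0])
    m1 = m2 = z = 0.0
    for state in itertools.product(range(q), repeat=n):
        s = np.array(state)
        energy = float(np.sum(graph.J * (s[edges[:, 0]] != s[edges[:, 1]])))
        w = np.exp(-energy / T)
        z += w
        g += w * (s[edges[:, 0]] == s[edges[:, 1]])
        counts = np.bincount(s, minlength=q)
        m = (q * counts.max() - n) / ((q - 1) * n)
        m1 += w * m
        m2 += w * m * m
    g /= z
    m1 /= z
    m2 /= z
    chi = n / T * (m2 - m1 * m1)
    return g, m1, chi


def exact_state_distribution(graph, q, T):
    """Exact Boltzmann probability of every spin state (for stationarity tests)."""
    n = graph.n
    edges = graph.edges
    states = list(itertools.product(range(q), repeat=n))
    w = np.array(
        [
            np.exp(
                -float(
                    np.sum(
                        graph.J
                        * (np.array(s)[edges[:, 0]] != np.array(s)[edges[:, 1]])
                    )
                )
                / T
            )
            for s in states
        ]
    )
    return states, w / w.sum()


def batch_mean_se(x, n_batches=50):
    """Batch-means estimate and standard error of a per-sweep series."""
    x = np.asarray(x, dtype=float)
    bs = x.shape[0] // n_batches
    b = x[: n_batches * bs].reshape(n_batches, bs, *x.shape[1:]).mean(axis=1)
    return b.mean(axis=0), b.std(axis=0, ddof=1) / np.sqrt(n_batches)


def jackknife_chi_se(m_samples, T, n_points, n_batches=50):
    """Delete-one-batch jackknife standard error of the susceptibility."""
    m = np.asarray(m_samples, dtype=float)
    bs = m.shape[0] // n_batches
    mb = m[: n_batches * bs].reshape(n_batches, bs)
    reps = np.array(
        [n_points / T * np.delete(mb, k, axis=0).ravel().var() for k in range(n_batches)]
    )
    return np.sqrt((n_batches - 1) / n_batches * np.sum((reps - reps.mean()) ** 2))
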
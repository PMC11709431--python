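"""Shared fixtures: small networks and an independent dense scattering oracle."""

import numpy as np
import pytest

from gapwave.network_io import Cell, GapJunctionEdge, GapJunctionNetwork, synthetic_random


def make_net(names, edges):
    """Build a network from (name_a, name_b, weight) tuples."""
    index = {n: i for i, n in enumerate(names)}
    cells = [Cell(i, n) for i, n in enumerate(names)]
    return GapJunctionNetwork(
        cells, [GapJunctionEdge(index[a], index[b], w) for a, b, w in edges]
    )


def dense_bordered_solve(net, in_cell, out_cell, E, gamma=5.0, a=1.0):
    """Independent oracle: assemble and solve the full bordered system densely.

    Reconstructs the circuit from first principles (cells, two virtual nodes
    per junction, hop weights 1 and min(1, g/40)) without using the package's
    circuit or solver code, and returns (r, t).
    """
    n_cells = net.n_cells
    n = n_cells + 2 * net.n_edges
    H = np.zeros((n, n))
    for e_rank, e in enumerate(net.edges):
        v1 = n_cells + 2 * e_rank
        v2 = v1 + 1
        w = min(1.0, e.weight / 40.0)
        for m, q, v in ((e.cell_a, v1, 1.0), (v1, v2, w), (v2, e.cell_b, 1.0)):
            H[m, q] = H[q, m] = v
    k = np.arccos(E / (2.0 * gamma)) / a
    sigma = np.exp(1j * k * a)
    M = H - E * np.eye(n) + 0j
    M[in_cell, in_cell] += sigma
    M[out_cell, out_cell] += sigma
    b = np.zeros(n, dtype=complex)
    b[in_cell] = sigma - np.conj(sigma)
    psi = np.linalg.solve(M, b)
    return psi[in_cell] - 1.0, psi[out_cell]


@pytest.fixture
def single_edge_half():
    """Two cells joined by one junction with anatomical weight 20 (hop w=0.5)."""
    return make_net(["A", "B"], [("A", "B", 20.0)])


@pytest.fixture
def random_net_factory():
    """Seeded random networks guaranteed to be connected-ish and nontrivial."""

    def factory(seed, n_cells=12, n_edges=None):
        if n_edges is None:
            n_edges = min(2 * n_cells, n_cells * (n_cells - 1) // 2)
        return synthetic_random(n_cells, n_edges, seed=seed)

    return factory
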
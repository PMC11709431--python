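"""Scattering circuit construction and the tight-binding Hamiltonian.

Each gap junction between cells i and j is expanded into a four-site segment
Cell-VN-VN-Cell by inserting two virtual nodes (VNs).  The cell-to-VN hops
model the intracellular conductor and carry hopping amplitude 1; the central
VN-to-VN hop models the junction itself and carries the processed weight
``w_ij = min(1, g_ij / 40)``, so junctions with anatomical weight >= 40
transmit perfectly across that hop.  All hops share the same nominal length
``a``; on-site energies are zero (the common resting potential is the energy
reference).  The resulting hopping matrix is the tight-binding Anderson
Hamiltonian of the circuit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network_io import GapJunctionNetwork

__all__ = [
    "processed_weight",
    "CircuitGraph",
    "build_circuit",
    "assemble_hamiltonian",
    "export_hamiltonian",
]

#: Anatomical weight at (and above) which the junction hop saturates at 1.
WEIGHT_SCALE = 40.0


def processed_weight(g) -> float | np.ndarray:
    """Junction hop amplitude ``w = min(1, g / 40)`` for anatomical weight g > 0."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("anatomical weight must be positive")
    w = np.minimum(1.0, g / WEIGHT_SCALE)
    return float(w) if w.ndim == 0 else w


@dataclass
class CircuitGraph:
    """Virtual-node-augmented circuit of a gap-junction network.

    Nodes 0..n_cells-1 are cells (source order); the two VNs of the e-th edge
    (input order) occupy indices ``n_cells + 2e`` and ``n_cells + 2e + 1``,
    the first adjacent to the edge's lower-indexed cell.  ``hops`` holds
    (node_m, node_n, V_mn) with V in (0, 1].
    """

    n_cells: int
    n_virtual: int
    labels: list[str]
    hops: list[tuple[int, int, float]]

    @property
    def n_nodes(self) -> int:
        return self.n_cells + self.n_virtual


def build_circuit(net: GapJunctionNetwork) -> CircuitGraph:
    """Expand every junction into Cell-VN-VN-Cell and collect the hops."""
    n = net.n_cells
    labels = list(net.names)
    hops: list[tuple[int, int, float]] = []
    for e, edge in enumerate(net.edges):
        v1 = n + 2 * e
        v2 = n + 2 * e + 1
        w = processed_weight(edge.weight)
        a_name, b_name = net.cells[edge.cell_a].name, net.cells[edge.cell_b].name
        labels.append(f"VN[{a_name}|{b_name}]a")
        labels.append(f"VN[{a_name}|{b_name}]b")
        hops.append((edge.cell_a, v1, 1.0))
        hops.append((v1, v2, w))
        hops.append((v2, edge.cell_b, 1.0))
    return CircuitGraph(n_cells=n, n_virtual=2 * net.n_edges, labels=labels, hops=hops)


def assemble_hamiltonian(circuit: CircuitGraph) -> sp.csr_matrix:
    """Symmetric sparse hopping matrix (zero diagonal) of the circuit."""
    n = circuit.n_nodes
    if not circuit.hops:
        return sp.csr_matrix((n, n))
    m, k, v = zip(*circuit.hops)
    rows = np.concatenate([m, k])
    cols = np.concatenate([k, m])
    vals = np.concatenate([v, v]).astype(float)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def export_hamiltonian(circuit: CircuitGraph, mtx_path, labels_path=None) -> None:
    """Write the Hamiltonian as Matrix Market and (optionally) a label CSV."""
    import scipy.io

    scipy.io.mmwrite(str(mtx_path), assemble_hamiltonian(circuit).tocoo(), symmetry="symmetric")
    if labels_path is not None:
        import csv

        with open(labels_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node", "label", "kind"])
            for i, lab in enumerate(circuit.labels):
                w.writerow([i, lab, "cell" if i < circuit.n_cells else "virtual"])
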
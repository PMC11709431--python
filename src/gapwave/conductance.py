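"""No-interference baseline: resistor-network effective conductance.

Treating every cell as a conducting node and every gap junction as a resistor
whose conductance equals the raw anatomical weight (``omega_ij = g_ij``,
arbitrary units), the two-point effective resistance under an external DC
source follows from Kirchhoff's and Ohm's laws via the weighted graph
Laplacian ``L_ij = delta_ij * sum_l omega_il - omega_ij``:

    R_eff(i, j) = (e_i - e_j)^T L^+ (e_i - e_j),    G_eff = 1 / R_eff,

with ``L^+`` the Moore-Penrose pseudoinverse.  Unlike the scattering model
this baseline ignores wave interference entirely: parallel paths always help
(Rayleigh monotonicity), so densely interconnected cells show high effective
conductance even where destructive interference suppresses wave transmission.

Note the intentional asymmetry with the scattering circuit: conductances use
the *raw* anatomical weights, not the processed hop weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .network_io import GapJunctionNetwork

__all__ = [
    "build_laplacian",
    "effective_resistance",
    "all_pairs_conductance",
    "voltage_profile",
    "VoltageProfile",
    "EffectiveConductanceMatrix",
]


def build_laplacian(net: GapJunctionNetwork) -> np.ndarray:
    """Weighted graph Laplacian of the resistor network (dense, symmetric PSD)."""
    n = net.n_cells
    L = np.zeros((n, n))
    for e in net.edges:
        w = e.weight
        L[e.cell_a, e.cell_b] -= w
        L[e.cell_b, e.cell_a] -= w
        L[e.cell_a, e.cell_a] += w
        L[e.cell_b, e.cell_b] += w
    return L


def _component_pinv(net: GapJunctionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Pseudoinverse of the Laplacian computed block-wise per component.

    Returns (L_plus, component_labels).  Working per connected component keeps
    the null space exactly one dimension per block and makes cross-component
    pairs exactly disconnected rather than numerically huge.
    """
    n = net.n_cells
    adj = sp.coo_matrix(
        (np.ones(net.n_edges), ([e.cell_a for e in net.edges], [e.cell_b for e in net.edges])),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    L = build_laplacian(net)
    Lp = np.zeros_like(L)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            continue
        block = np.linalg.pinv(L[np.ix_(idx, idx)], hermitian=True)
        Lp[np.ix_(idx, idx)] = (block + block.T) / 2.0  # exact symmetry
    return Lp, labels


def effective_resistance(net: GapJunctionNetwork, i: int, j: int) -> float:
    """Two-point effective resistance; ``inf`` across components, 0 for i == j."""
    if i == j:
        return 0.0
    Lp, labels = _component_pinv(net)
    if labels[i] != labels[j]:
        return math.inf
    return float(Lp[i, i] + Lp[j, j] - 2.0 * Lp[i, j])


@dataclass
class EffectiveConductanceMatrix:
    """Symmetric all-pairs effective conductance (arbitrary units).

    ``G[i, j] = 0`` exactly when i and j lie in different components; the
    diagonal is zero by convention (self-conductance is not defined).
    """

    G: np.ndarray
    names: list[str]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.G, index=self.names, columns=self.names)


def all_pairs_conductance(net: GapJunctionNetwork) -> EffectiveConductanceMatrix:
    """Effective conductance for every unordered pair from one pseudoinverse.

    ``R_eff(i, j) = L+_ii + L+_jj - 2 L+_ij`` makes the all-pairs sweep O(1)
    per pair after the single pseudoinverse.
    """
    Lp, labels = _component_pinv(net)
    d = np.diag(Lp)
    R = d[:, None] + d[None, :] - 2.0 * Lp
    same = labels[:, None] == labels[None, :]
    G = np.zeros_like(R)
    off = ~np.eye(net.n_cells, dtype=bool)
    ok = same & off & (R > 0)
    G[ok] = 1.0 / R[ok]
    return EffectiveConductanceMatrix(G=G, names=net.names)


@dataclass
class VoltageProfile:
    """Node voltages for one unit of injected current between a source/sink pair."""

    source: int
    sink: int
    current: float
    voltages: np.ndarray

    def kcl_residual(self, net: GapJunctionNetwork) -> float:
        """Max deviation of net nodal current from (+I, -I, 0) by Ohm's law."""
        n = net.n_cells
        net_current = np.zeros(n)
        for e in net.edges:
            mu = e.weight * (self.voltages[e.cell_a] - self.voltages[e.cell_b])
            net_current[e.cell_a] += mu
            net_current[e.cell_b] -= mu
        expected = np.zeros(n)
        expected[self.source] = self.current
        expected[self.sink] = -self.current
        return float(np.abs(net_current - expected).max())


def voltage_profile(net: GapJunctionNetwork, source: int, sink: int,
                    current: float = 1.0) -> VoltageProfile:
    """Solve ``L v = I (e+ - e-)`` via the pseudoinverse (zero-mean solution)."""
    if source == sink:
        raise ValueError("source and sink must differ")
    Lp, labels = _component_pinv(net)
    if labels[source] != labels[sink]:
        raise ValueError("source and sink are in different components; no steady state")
    rhs = np.zeros(net.n_cells)
    rhs[source] = current
    rhs[sink] = -current
    return VoltageProfile(source, sink, current, Lp @ rhs)
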
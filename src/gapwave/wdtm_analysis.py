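"""Downstream statistics of transmission spectra.

Covers the pair-averaged transmission curve, the signal mobility edge (the
energy magnitude beyond which transmission effectively vanishes), extraction
of wavenumber-dependent transmission maps (WDTMs: the set of strongly
transmitting cell pairs at one energy), selection of the energies at which
WDTMs are read out, appearance-rate hub statistics across the selected
energies, and shortest-path distance patterns (including the common-divisor
regularities seen along linear muscle strands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .network_io import GapJunctionNetwork
from .scattering import TransmissionSpectrum

__all__ = [
    "TransmissionCurve",
    "WDTM",
    "AppearanceRateMatrix",
    "average_transmission",
    "find_mobility_edge",
    "strong_pairs",
    "select_wdtm_energies",
    "appearance_rate",
    "find_hubs",
    "pair_distance",
    "all_pair_distances",
    "strand_pattern",
    "StrandPatternReport",
]

#: Reference level below which pair-averaged transmission counts as vanished:
#: roughly one pair in 1e5 transmitting at 1%.
MOBILITY_EDGE_THRESHOLD = 1e-7

#: Strong-transmission cutoff defining WDTM membership (strict T > cutoff).
STRONG_CUTOFF = 0.5


@dataclass
class TransmissionCurve:
    """Pair-averaged transmission as a function of energy."""

    E_grid: np.ndarray
    mean_T: np.ndarray

    def __post_init__(self):
        if self.E_grid.shape != self.mean_T.shape:
            raise ValueError("grid and values must align")


def average_transmission(spectrum: TransmissionSpectrum) -> TransmissionCurve:
    """Arithmetic mean of T over all unordered pairs, per grid energy."""
    return TransmissionCurve(E_grid=spectrum.E_grid.copy(),
                             mean_T=spectrum.mean_transmission())


def find_mobility_edge(curve: TransmissionCurve,
                       threshold: float = MOBILITY_EDGE_THRESHOLD
                       ) -> tuple[float, float] | None:
    """Energies beyond which the mean transmission stays at or below threshold.

    The positive edge ``E+`` is the smallest positive grid energy such that
    every grid point at or beyond it satisfies ``mean_T <= threshold``; the
    negative edge is the symmetric counterpart.  Persistence (rather than
    first crossing) makes the edge robust to isolated resonant peaks in the
    decaying tail.  Returns ``None`` when no such energies exist on the grid.
    """
    E, y = curve.E_grid, curve.mean_T
    below = y <= threshold
    # positive edge: smallest positive E whose entire right tail is below
    pos = np.flatnonzero(E > 0)
    e_plus = None
    for idx in pos[::-1]:
        if not below[idx]:
            break
        e_plus = float(E[idx])
    # negative edge: largest negative E whose entire left tail is below
    neg = np.flatnonzero(E < 0)
    e_minus = None
    for idx in neg:
        if not below[idx]:
            break
        e_minus = float(E[idx])
    if e_plus is None or e_minus is None:
        return None
    return (e_minus, e_plus)


@dataclass
class WDTM:
    """Strong-transmission pair set at one energy (the transmission map).

    ``pairs`` holds unordered (i, j) cell-index tuples with ``T > cutoff``
    (strict); ``T`` maps each stored pair to its coefficient.
    """

    E: float
    cutoff: float
    pairs: list[tuple[int, int]]
    T: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def cells(self) -> set[int]:
        return {c for p in self.pairs for c in p}


def strong_pairs(spectrum: TransmissionSpectrum, E: float,
                 cutoff: float = STRONG_CUTOFF) -> WDTM:
    """Pairs with ``T(E) > cutoff`` (strict) at one grid energy."""
    col = spectrum._grid_index(E)
    mask = spectrum.T[:, col] > cutoff
    idx = np.flatnonzero(mask)
    pairs = [(int(spectrum.pair_i[m]), int(spectrum.pair_j[m])) for m in idx]
    return WDTM(E=float(E), cutoff=cutoff, pairs=pairs,
                T={p: float(spectrum.T[m, col]) for p, m in zip(pairs, idx)})


def select_wdtm_energies(curve: TransmissionCurve, spectrum: TransmissionSpectrum,
                         cutoff: float = STRONG_CUTOFF) -> list[float]:
    """Energies at which transmission maps are read out.

    Three criteria: (1) the mean-transmission curve has a local maximum at
    the energy (strictly above both neighbours; a plateau counts once, at its
    leftmost point, provided it dominates both flanks), (2) at least one pair
    exceeds the strong-transmission cutoff there, and (3) the energy is
    positive (the curve is symmetric, so negative peaks are redundant).
    """
    if not np.array_equal(curve.E_grid, spectrum.E_grid):
        raise ValueError("curve and spectrum must share the energy grid")
    y = curve.mean_T
    E = curve.E_grid
    n = y.size
    selected: list[float] = []
    m = 0
    while m < n:
        # find plateau [m, q] of equal values
        q = m
        while q + 1 < n and y[q + 1] == y[m]:
            q += 1
        left_ok = m > 0 and y[m - 1] < y[m]
        right_ok = q < n - 1 and y[q + 1] < y[m]
        if left_ok and right_ok and E[m] > 0:
            col = m
            if (spectrum.T[:, col] > cutoff).any():
                selected.append(float(E[m]))
        m = q + 1
    return selected


@dataclass
class AppearanceRateMatrix:
    """Per-pair appearance rates across the selected energies.

    ``rate`` is the mean of the step statistic ``theta[T - cutoff]`` (with
    ``theta[0] = 1``) over the selected energy set, so every value is an
    exact multiple of ``1/m`` for ``m`` energies.
    """

    energies: list[float]
    pair_i: np.ndarray
    pair_j: np.ndarray
    rate: np.ndarray
    n_cells: int

    def matrix(self) -> np.ndarray:
        m = np.zeros((self.n_cells, self.n_cells))
        m[self.pair_i, self.pair_j] = self.rate
        m[self.pair_j, self.pair_i] = self.rate
        return m


def appearance_rate(spectrum: TransmissionSpectrum, energies: Sequence[float],
                    cutoff: float = STRONG_CUTOFF) -> AppearanceRateMatrix:
    """Mean of ``theta[T(E) - cutoff]`` over the selected energies, per pair.

    The step function has ``theta[0] = 1``, so a pair sitting exactly at the
    cutoff counts as an appearance even though WDTM membership is strict.
    """
    if len(energies) == 0:
        raise ValueError("need at least one selected energy")
    cols = [spectrum._grid_index(E) for E in energies]
    hits = spectrum.T[:, cols] >= cutoff  # theta[x] = 1 iff x >= 0
    return AppearanceRateMatrix(
        energies=[float(E) for E in energies],
        pair_i=spectrum.pair_i.copy(), pair_j=spectrum.pair_j.copy(),
        rate=hits.mean(axis=1), n_cells=spectrum.n_cells,
    )


def find_hubs(rates: AppearanceRateMatrix, threshold: float,
              names: Sequence[str] | None = None) -> list[dict]:
    """Pairs with appearance rate >= threshold, highest rate first.

    Ties are broken lexicographically on the (name) pair.  Each record holds
    the cell indices, names when available, and the rate.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    keep = np.flatnonzero(rates.rate >= threshold)
    label = (lambda i: names[i]) if names is not None else (lambda i: str(i))
    records = [
        {"cell_a": int(rates.pair_i[m]), "cell_b": int(rates.pair_j[m]),
         "name_a": label(int(rates.pair_i[m])), "name_b": label(int(rates.pair_j[m])),
         "rate": float(rates.rate[m])}
        for m in keep
    ]
    records.sort(key=lambda r: (-r["rate"], r["name_a"], r["name_b"]))
    return records


def pair_distance(net: GapJunctionNetwork, i: int, j: int) -> float:
    """Unweighted shortest-path length on the cell graph; inf if disconnected."""
    if i == j:
        return 0
    g = net.to_networkx()
    try:
        return nx.shortest_path_length(g, i, j)
    except nx.NetworkXNoPath:
        return math.inf


def all_pair_distances(net: GapJunctionNetwork,
                       pairs: Sequence[tuple[int, int]]) -> dict[tuple[int, int], float]:
    """Shortest-path distance for a batch of pairs (one BFS per source cell)."""
    g = net.to_networkx()
    sources = {p[0] for p in pairs}
    lengths = {s: nx.single_source_shortest_path_length(g, s) for s in sources}
    return {p: float(lengths[p[0]].get(p[1], math.inf)) for p in pairs}


@dataclass
class StrandPatternReport:
    """Distance regularity of a transmission map restricted to one strand."""

    strand: str
    distances: list[int]
    gcd: int | None
    all_multiples: bool

    @property
    def nontrivial(self) -> bool:
        return self.gcd is not None and self.gcd > 1


def strand_pattern(wdtm: WDTM, net: GapJunctionNetwork,
                   strand_membership: Mapping[str, Sequence[int]]
                   ) -> list[StrandPatternReport]:
    """Per-strand distance multisets of a WDTM and their common divisor.

    ``strand_membership`` maps a strand label to the ordered cell indices of
    that strand.  The WDTM is restricted to intra-strand pairs; the report
    gives the multiset of network shortest-path distances, their gcd, and
    whether all distances are multiples of it (true by construction whenever
    the gcd exists; kept explicit for readability of downstream tables).
    """
    reports = []
    for label, members in strand_membership.items():
        mem = set(members)
        intra = [p for p in wdtm.pairs if p[0] in mem and p[1] in mem]
        dists = all_pair_distances(net, intra) if intra else {}
        finite = sorted(int(d) for d in dists.values() if math.isfinite(d))
        g = math.gcd(*finite) if finite else None
        reports.append(StrandPatternReport(
            strand=label, distances=finite, gcd=g,
            all_multiples=bool(finite) and all(d % g == 0 for d in finite),
        ))
    return reports
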
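"""Gap-junction network containers, file I/O and synthetic generators.

A gap-junction (electrical synapse) network is an undirected weighted graph:
nodes are cells, edges are gap junctions, and the edge weight ``g_ij`` is the
anatomical junction weight (proportional to the structural size of the
junction).  Networks are read from the connectome adjacency-matrix workbook
dialect or from plain CSV edge lists, and synthetic networks with the
statistical structure of the real connectome (heavy-tailed integer weights,
linear muscle strands, an hmc-like hub, a dense random core) can be generated
for testing and simulation studies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "Cell",
    "GapJunctionEdge",
    "GapJunctionNetwork",
    "read_connectome_workbook",
    "read_edge_list",
    "write_edge_list",
    "read_cell_types",
    "generate_synthetic",
    "synthetic_chain",
    "synthetic_ring",
    "synthetic_strand_bundle",
    "synthetic_random",
    "synthetic_connectome",
    "network_summary",
    "write_graphml",
    "log_uniform_weights",
]

#: The seven anatomical cell classes of the hermaphrodite connectome.
CELL_TYPES = (
    "pharynx",
    "sensory",
    "inter",
    "motor",
    "body_wall_muscle",
    "other_end_organ",
    "sex_specific",
)

#: Maximum anatomical weight observed in the reference connectome; the
#: default synthetic weight sampler draws log-uniform integers on [1, 401].
WEIGHT_RANGE = (1, 401)


@dataclass(frozen=True)
class Cell:
    """A cell (node) of the network.

    ``index`` is the 0-based ordinal in source order; ``cell_type`` is one of
    :data:`CELL_TYPES` or ``"unknown"`` when no metadata is supplied.
    """

    index: int
    name: str
    cell_type: str = "unknown"


@dataclass(frozen=True)
class GapJunctionEdge:
    """An undirected gap junction with anatomical weight ``weight`` > 0.

    Stored canonically with ``cell_a < cell_b`` (cell indices).
    """

    cell_a: int
    cell_b: int
    weight: float


class GapJunctionNetwork:
    """A validated, canonicalized gap-junction network.

    Parameters
    ----------
    cells
        Cells in source order; names must be unique and indices contiguous.
    edges
        Undirected edges; endpoints are canonicalized to ``cell_a < cell_b``
        preserving input order.  Self-loops, non-positive weights and
        duplicate unordered pairs raise ``ValueError``.
    """

    def __init__(self, cells: Sequence[Cell], edges: Iterable[GapJunctionEdge]):
        cells = list(cells)
        names = [c.name for c in cells]
        if len(set(names)) != len(names):
            raise ValueError("cell names must be unique")
        for i, c in enumerate(cells):
            if c.index != i:
                raise ValueError(f"cell indices must be contiguous 0..N-1, got {c.index} at {i}")
        self.cells: list[Cell] = cells

        canon: list[GapJunctionEdge] = []
        seen: set[tuple[int, int]] = set()
        n = len(cells)
        for e in edges:
            a, b = e.cell_a, e.cell_b
            if a == b:
                raise ValueError(f"self-loop on cell {a} ({cells[a].name})")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge endpoint out of range: ({a}, {b})")
            if e.weight <= 0:
                raise ValueError(f"non-positive weight {e.weight} on edge ({a}, {b})")
            if a > b:
                a, b = b, a
            if (a, b) in seen:
                raise ValueError(f"duplicate edge for unordered pair ({a}, {b})")
            seen.add((a, b))
            canon.append(GapJunctionEdge(a, b, float(e.weight)))
        self.edges: list[GapJunctionEdge] = canon

    # -- basic queries ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cells]

    def name_to_index(self) -> dict[str, int]:
        return {c.name: c.index for c in self.cells}

    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.edges], dtype=float)

    def degree(self) -> np.ndarray:
        """Gap-junction degree of every cell."""
        d = np.zeros(self.n_cells, dtype=int)
        for e in self.edges:
            d[e.cell_a] += 1
            d[e.cell_b] += 1
        return d

    def with_cell_types(self, types: Mapping[str, str]) -> "GapJunctionNetwork":
        """Return a copy with ``cell_type`` filled from a name->type mapping."""
        cells = [
            Cell(c.index, c.name, types.get(c.name, c.cell_type)) for c in self.cells
        ]
        return GapJunctionNetwork(cells, self.edges)

    def to_networkx(self) -> nx.Graph:
        """Cell-level graph (no virtual nodes) with ``weight`` edge attrs."""
        g = nx.Graph()
        for c in self.cells:
            g.add_node(c.index, name=c.name, cell_type=c.cell_type)
        for e in self.edges:
            g.add_edge(e.cell_a, e.cell_b, weight=e.weight)
        return g

    def adjacency(self) -> np.ndarray:
        """Dense symmetric anatomical-weight adjacency matrix."""
        a = np.zeros((self.n_cells, self.n_cells))
        for e in self.edges:
            a[e.cell_a, e.cell_b] = e.weight
            a[e.cell_b, e.cell_a] = e.weight
        return a

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GapJunctionNetwork(n_cells={self.n_cells}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_connectome_workbook(path, sheet_name: str = "hermaphrodite gap jn symmetric") -> GapJunctionNetwork:
    """Read a symmetric adjacency-matrix tab of a connectome workbook.

    The dialect is: first row and first column hold cell names, the numeric
    body holds junction weights, zero meaning "no junction".  The tab is
    declared symmetric; any asymmetry beyond exact equality is an error.
    One edge is emitted per strictly-upper-triangle nonzero, preserving the
    header cell order.
    """
    df = pd.read_excel(path, sheet_name=sheet_name, header=0, index_col=0, engine="openpyxl")
    row_names = [str(x) for x in df.index]
    col_names = [str(x) for x in df.columns]
    if len(row_names) != len(col_names) or row_names != col_names:
        raise ValueError("adjacency tab is not square with matching row/column headers")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise ValueError("adjacency tab contains non-numeric cells")
    if np.isnan(body).any():
        body = np.nan_to_num(body, nan=0.0)
    if not np.array_equal(body, body.T):
        i, j = np.argwhere(body != body.T)[0]
        raise ValueError(
            f"asymmetric entries at ({row_names[i]}, {col_names[j]}): "
            f"{body[i, j]} vs {body[j, i]}"
        )
    cells = [Cell(i, nm) for i, nm in enumerate(row_names)]
    ii, jj = np.nonzero(np.triu(body, k=1))
    edges = [GapJunctionEdge(int(a), int(b), float(body[a, b])) for a, b in zip(ii, jj)]
    return GapJunctionNetwork(cells, edges)


def read_edge_list(path, merge: str | None = None) -> GapJunctionNetwork:
    """Read a ``cell_a,cell_b,weight`` CSV edge list.

    Cells are indexed in first-appearance order.  Duplicate unordered pairs
    are an error unless ``merge="sum"`` is given, in which case their weights
    are summed.
    """
    df = pd.read_csv(path, dtype={"cell_a": str, "cell_b": str})
    required = {"cell_a", "cell_b", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")

    index: dict[str, int] = {}
    cells: list[Cell] = []

    def idx(name: str) -> int:
        if name not in index:
            index[name] = len(cells)
            cells.append(Cell(len(cells), name))
        return index[name]

    acc: dict[tuple[int, int], float] = {}
    order: list[tuple[int, int]] = []
    for row in df.itertuples(index=False):
        a, b = idx(row.cell_a), idx(row.cell_b)
        w = float(row.weight)
        if a == b:
            raise ValueError(f"self-loop on cell {row.cell_a}")
        if w <= 0:
            raise ValueError(f"non-positive weight {w} on ({row.cell_a}, {row.cell_b})")
        key = (min(a, b), max(a, b))
        if key in acc:
            if merge == "sum":
                acc[key] += w
            else:
                raise ValueError(
                    f"duplicate edge ({row.cell_a}, {row.cell_b}); pass merge='sum' to combine"
                )
        else:
            acc[key] = w
            order.append(key)
    edges = [GapJunctionEdge(a, b, acc[(a, b)]) for a, b in order]
    return GapJunctionNetwork(cells, edges)


def write_edge_list(net: GapJunctionNetwork, path) -> None:
    """Write the canonical CSV edge list (``cell_a,cell_b,weight`` by name)."""
    names = net.names
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_a", "cell_b", "weight"])
        for e in net.edges:
            weight = int(e.weight) if float(e.weight).is_integer() else e.weight
            w.writerow([names[e.cell_a], names[e.cell_b], weight])


def read_cell_types(path) -> dict[str, str]:
    """Read a two-column ``name,cell_type`` metadata CSV."""
    df = pd.read_csv(path, dtype=str)
    if not {"name", "cell_type"}.issubset(df.columns):
        raise ValueError("metadata CSV must have columns name,cell_type")
    return dict(zip(df["name"], df["cell_type"]))


def write_graphml(net: GapJunctionNetwork, path) -> None:
    """Export as GraphML (node attrs name/cell_type, edge attr weight)."""
    nx.write_graphml(net.to_networkx(), path)


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

def log_uniform_weights(rng: np.random.Generator, size: int,
                        low: int = WEIGHT_RANGE[0], high: int = WEIGHT_RANGE[1]) -> np.ndarray:
    """Integer weights log-uniform on [low, high].

    Mirrors the heavy-tailed anatomical weight distribution: most junctions
    are small, a few are two orders of magnitude larger.
    """
    u = rng.uniform(np.log(low), np.log(high + 1), size=size)
    return np.minimum(np.floor(np.exp(u)).astype(int), high)


def synthetic_chain(n: int, weight: float = 40.0, prefix: str = "A") -> GapJunctionNetwork:
    """A path of ``n`` cells with uniform junction weight."""
    cells = [Cell(i, f"{prefix}{i}") for i in range(n)]
    edges = [GapJunctionEdge(i, i + 1, weight) for i in range(n - 1)]
    return GapJunctionNetwork(cells, edges)


def synthetic_ring(n: int, weight: float = 40.0, prefix: str = "R") -> GapJunctionNetwork:
    """A cycle of ``n`` cells with uniform junction weight."""
    if n < 3:
        raise ValueError("ring needs at least 3 cells")
    cells = [Cell(i, f"{prefix}{i}") for i in range(n)]
    edges = [GapJunctionEdge(i, (i + 1) % n, weight) for i in range(n)]
    return GapJunctionNetwork(cells, edges)


#: Strand naming follows the body-wall muscle convention: four strands
#: (dorsal/ventral x left/right) of 24 muscles each in the real animal.
_STRAND_PREFIXES = ("dBWML", "dBWMR", "vBWML", "vBWMR")


def synthetic_strand_bundle(n_strands: int = 4, strand_len: int = 24,
                            hub_weight: float = 300.0, strand_weight: float = 100.0,
                            ) -> GapJunctionNetwork:
    """Linear muscle strands plus one hub cell on every strand's neck.

    Each strand is a chain of ``strand_len`` muscle cells; a single hub cell
    (named ``hmc`` after the head mesodermal cell it emulates) is attached to
    the seventh and eighth muscle of every strand with weight ``hub_weight``.
    """
    if strand_len < 8:
        raise ValueError("strand_len must be >= 8 to attach the hub at muscles 7 and 8")
    cells: list[Cell] = []
    edges: list[GapJunctionEdge] = []
    for s in range(n_strands):
        prefix = _STRAND_PREFIXES[s] if s < len(_STRAND_PREFIXES) else f"strand{s}_"
        base = len(cells)
        for m in range(strand_len):
            cells.append(Cell(len(cells), f"{prefix}{m + 1}", "body_wall_muscle"))
        for m in range(strand_len - 1):
            edges.append(GapJunctionEdge(base + m, base + m + 1, strand_weight))
    hub = len(cells)
    cells.append(Cell(hub, "hmc", "other_end_organ"))
    for s in range(n_strands):
        base = s * strand_len
        # neck attachment: 7th and 8th muscle (1-based) of each strand
        edges.append(GapJunctionEdge(base + 6, hub, hub_weight))
        edges.append(GapJunctionEdge(base + 7, hub, hub_weight))
    return GapJunctionNetwork(cells, edges)


def synthetic_random(n_cells: int, n_edges: int, seed: int | None = None,
                     weight_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                     prefix: str = "N") -> GapJunctionNetwork:
    """A uniform random simple graph with sampled junction weights.

    Deterministic for a fixed ``seed``; the default weight sampler is
    log-uniform integers on [1, 401].
    """
    max_edges = n_cells * (n_cells - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceeds simple-graph maximum {max_edges}")
    rng = np.random.default_rng(seed)
    cells = [Cell(i, f"{prefix}{i}") for i in range(n_cells)]
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    chosen.sort()
    iu, ju = np.triu_indices(n_cells, k=1)
    sampler = weight_sampler or log_uniform_weights
    w = np.asarray(sampler(rng, n_edges), dtype=float)
    edges = [GapJunctionEdge(int(iu[c]), int(ju[c]), float(w[m])) for m, c in enumerate(chosen)]
    return GapJunctionNetwork(cells, edges)


def synthetic_connectome(seed: int = 0, n_cells: int = 469, n_edges: int = 1433,
                         n_strands: int = 4, strand_len: int = 24,
                         hub_weight: float = 300.0) -> GapJunctionNetwork:
    """Connectome-scale composite fixture.

    Combines the anatomical motifs of the hermaphrodite gap-junction network:
    four linear body-wall-muscle strands of 24 cells, an hmc-like hub wired to
    each strand's neck (muscles 7 and 8), and a dense random "neuron" core
    over the remaining cells with log-uniform integer weights on [1, 401].
    Defaults give exactly 469 cells and 1433 edges.
    """
    rng = np.random.default_rng(seed)
    bundle = synthetic_strand_bundle(n_strands, strand_len, hub_weight=hub_weight,
                                     strand_weight=float(rng.integers(60, 140)))
    cells = list(bundle.cells)
    edges = list(bundle.edges)
    n_core = n_cells - len(cells)
    if n_core < 0:
        raise ValueError("n_cells smaller than the muscle bundle")
    core_base = len(cells)
    for i in range(n_core):
        cells.append(Cell(len(cells), f"N{i}", "unknown"))
    n_rand = n_edges - len(edges)
    if n_rand < 0:
        raise ValueError("n_edges smaller than the bundle edge count")
    # random core edges, plus a few core-to-muscle bridges so the network is
    # not trivially split between muscles and neurons
    seen = {(e.cell_a, e.cell_b) for e in edges}
    w = log_uniform_weights(rng, n_rand)
    n_bridge = min(n_rand // 20, core_base)
    made = 0
    while made < n_rand:
        if made < n_bridge:
            a = int(rng.integers(0, core_base))
            b = int(rng.integers(core_base, n_cells))
        else:
            a = int(rng.integers(core_base, n_cells))
            b = int(rng.integers(core_base, n_cells))
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append(GapJunctionEdge(key[0], key[1], float(w[made])))
        made += 1
    return GapJunctionNetwork(cells, edges)


_GENERATORS = {
    "chain": synthetic_chain,
    "ring": synthetic_ring,
    "strand_bundle": synthetic_strand_bundle,
    "random": synthetic_random,
    "connectome": synthetic_connectome,
}


def generate_synthetic(kind: str, seed: int | None = None, **params) -> GapJunctionNetwork:
    """Dispatch to a named synthetic topology.

    ``kind`` is one of ``chain``, ``ring``, ``strand_bundle``, ``random``,
    ``connectome``.  ``seed`` is forwarded to the stochastic generators and
    ignored by the deterministic ones.
    """
    try:
        fn = _GENERATORS[kind]
    except KeyError:
        raise ValueError(f"unknown topology {kind!r}; choose from {sorted(_GENERATORS)}")
    if kind in ("random", "connectome"):
        params["seed"] = seed
    return fn(**params)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    n_cells: int
    n_edges: int
    weight_min: float | None
    weight_max: float | None
    histogram_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    histogram_edges: np.ndarray = field(default_factory=lambda: np.array([]))


def network_summary(net: GapJunctionNetwork, bins=20) -> NetworkSummary:
    """Counts and the weight histogram of a network."""
    w = net.weights()
    if w.size == 0:
        return NetworkSummary(net.n_cells, 0, None, None)
    counts, edges = np.histogram(w, bins=bins)
    return NetworkSummary(net.n_cells, net.n_edges, float(w.min()), float(w.max()),
                          counts, edges)
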
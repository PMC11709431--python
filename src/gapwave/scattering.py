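"""Injector/detector wave scattering on the circuit Hamiltonian.

A monochromatic wave with wavenumber ``k`` (energy ``E = 2*gamma*cos(k*a)``)
is injected at one cell through a perfect lead of length ``a`` and detected
at another.  Writing the wave on the injected cell as ``psi_IN = 1 + r`` and
on the detector cell as ``psi_OUT = t``, the stationary condition
``H psi + phi_lead = E psi`` reduces to a bordered complex linear system: the
interior rows are ``(H - E I) psi = 0`` while the IN and OUT rows acquire a
lead self-energy ``exp(i k a)`` on the diagonal, and the only source term is
``exp(ika) - exp(-ika) = 2i sin(ka)`` on the IN row.  ``T = |t|^2`` and
``R = |r|^2`` are the transmission and reflection coefficients; the circuit
is lossless so ``T + R = 1`` up to numerical error.

Two solution paths are provided.  The *direct* path assembles and solves the
bordered system for one (IN, OUT, E) at a time.  The *fast* path notes that
the lead self-energies are a rank-2 diagonal update of the pair-independent
interior operator ``A = H - E I``: with ``S`` the cell-block of ``A^{-1}``,
``sigma = exp(ika)`` and ``beta = 2i sin(ka)``, eliminating the interior
nodes leaves the 2x2 system ``(I + sigma*C) [psi_IN, psi_OUT] = beta*[S_ii,
S_ij]`` with ``C = [[S_ii, S_ij], [S_ij, S_jj]]``, i.e.

    t = beta * S_ij / det,
    r = beta * (S_ii * (1 + sigma*S_jj) - sigma*S_ij**2) / det - 1,
    det = (1 + sigma*S_ii) * (1 + sigma*S_jj) - sigma**2 * S_ij**2,

so one factorization of ``A`` per energy serves every cell pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .circuit_model import CircuitGraph, assemble_hamiltonian

__all__ = [
    "ScatteringConfig",
    "ScatteringResult",
    "TransmissionSpectrum",
    "TransmissionSolver",
    "energy_from_wavenumber",
    "wavenumber_from_energy",
    "make_energy_grid",
    "solve_pair",
    "all_pairs_transmission",
    "compute_spectrum",
    "conservation_policy",
    "gamma_sweep",
]

_DENSE_LIMIT = 600  # components up to this many nodes use dense LAPACK solves


@dataclass(frozen=True)
class ScatteringConfig:
    """Parameters of the scattering calculation.

    gamma : lead/tight-binding energy scale; the band is ``[-2*gamma, 2*gamma]``.
    a : lattice spacing (pure convention; wavenumbers are in radians per edge).
    conservation_tolerance : post-correction threshold on ``|T + R - 1|``.
    band_edge_policy : at ``|E| = 2*gamma`` the incident flux ``2i sin(ka)``
        vanishes; ``"zero"`` reports (T, R) = (0, 1) without solving, ``"skip"``
        returns no result.
    """

    gamma: float = 5.0
    a: float = 1.0
    conservation_tolerance: float = 1e-5
    band_edge_policy: str = "zero"

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.band_edge_policy not in ("zero", "skip"):
            raise ValueError("band_edge_policy must be 'zero' or 'skip'")

    @property
    def band(self) -> tuple[float, float]:
        return (-2.0 * self.gamma, 2.0 * self.gamma)


@dataclass
class ScatteringResult:
    """Complex amplitudes and coefficients of one (IN, OUT, E) solve."""

    in_cell: int
    out_cell: int
    E: float
    k: float
    r: complex
    t: complex
    T: float
    R: float
    conservation_error: float
    corrected: bool = False
    flagged: bool = False  # least-squares fallback was used


def energy_from_wavenumber(k: float, cfg: ScatteringConfig) -> float:
    """Dispersion relation ``E = 2*gamma*cos(k*a)`` for ``k`` in [0, pi/a]."""
    if not 0 <= k <= math.pi / cfg.a + 1e-12:
        raise ValueError("wavenumber must lie in [0, pi/a]")
    return 2.0 * cfg.gamma * math.cos(k * cfg.a)


def wavenumber_from_energy(E: float, cfg: ScatteringConfig) -> float:
    """Inverse dispersion ``k = arccos(E / (2*gamma)) / a`` on ``|E| <= 2*gamma``."""
    x = E / (2.0 * cfg.gamma)
    if abs(x) > 1 + 1e-12:
        raise ValueError(f"energy {E} outside the band [{-2 * cfg.gamma}, {2 * cfg.gamma}]")
    return math.acos(min(1.0, max(-1.0, x))) / cfg.a


def make_energy_grid(e_min: float = -10.0, e_max: float = 10.0, de: float = 0.025,
                     cfg: ScatteringConfig | None = None) -> np.ndarray:
    """Inclusive arithmetic energy grid; defaults give 801 points on [-10, 10].

    The grid must stay inside the band ``[-2*gamma, 2*gamma]`` of ``cfg``.
    """
    cfg = cfg or ScatteringConfig()
    if e_min >= e_max:
        raise ValueError("e_min must be below e_max")
    if de <= 0:
        raise ValueError("de must be positive")
    lo, hi = cfg.band
    if e_min < lo - 1e-9 or e_max > hi + 1e-9:
        raise ValueError(f"grid [{e_min}, {e_max}] exceeds the band [{lo}, {hi}]")
    n = int(round((e_max - e_min) / de)) + 1
    grid = e_min + de * np.arange(n)
    grid[-1] = min(grid[-1], hi)
    return grid


def _is_band_edge(E: float, cfg: ScatteringConfig) -> bool:
    return abs(abs(E) - 2.0 * cfg.gamma) <= 1e-12


class TransmissionSolver:
    """Scattering solver bound to one circuit and configuration.

    Precomputes the Hamiltonian and the connected components of the circuit;
    exposes per-pair solves, the factorized all-pairs path, and full-grid
    spectra.
    """

    def __init__(self, circuit: CircuitGraph, config: ScatteringConfig | None = None):
        self.circuit = circuit
        self.config = config or ScatteringConfig()
        self.H = assemble_hamiltonian(circuit).tocsr()
        self.n_cells = circuit.n_cells
        n_comp, labels = connected_components(self.H, directed=False)
        self._comp_of = labels
        self._components: list[np.ndarray] = [
            np.flatnonzero(labels == c) for c in range(n_comp)
        ]
        self._eig_cache: dict[int, tuple] = {}

    # -- direct bordered solve -------------------------------------------

    def solve_pair(self, in_cell: int, out_cell: int, E: float) -> ScatteringResult | None:
        cfg = self.config
        if in_cell == out_cell:
            raise ValueError("IN and OUT cells must differ")
        if not (0 <= in_cell < self.n_cells and 0 <= out_cell < self.n_cells):
            raise ValueError("IN/OUT must be cell (not virtual) nodes")
        lo, hi = cfg.band
        if E < lo - 1e-9 or E > hi + 1e-9:
            raise ValueError(f"energy {E} outside the band [{lo}, {hi}]")
        k = wavenumber_from_energy(E, cfg)
        if _is_band_edge(E, cfg):
            if cfg.band_edge_policy == "skip":
                return None
            return ScatteringResult(in_cell, out_cell, E, k, -1.0 + 0j, 0j, 0.0, 1.0, 0.0)
        if self._comp_of[in_cell] != self._comp_of[out_cell]:
            return ScatteringResult(in_cell, out_cell, E, k, -1.0 + 0j, 0j, 0.0, 1.0, 0.0)

        nodes = self._components[self._comp_of[in_cell]]
        pos = {g: p for p, g in enumerate(nodes)}
        sub = self.H[nodes][:, nodes]
        n = len(nodes)
        sigma = np.exp(1j * k * cfg.a)
        beta = sigma - np.conj(sigma)
        p_in, p_out = pos[in_cell], pos[out_cell]

        diag = np.full(n, -E, dtype=complex)
        diag[p_in] += sigma
        diag[p_out] += sigma
        M = sub.astype(complex) + sp.diags(diag)
        b = np.zeros(n, dtype=complex)
        b[p_in] = beta

        # When E hits an eigenvalue of H the bordered system is exactly rank
        # deficient; its null vectors carry no weight on the lead cells, so
        # the minimum-norm solution is the physical one (it equals the
        # E -> eigenvalue limit), whereas a plain LU solve silently adds an
        # arbitrary null component.  The dense path therefore always solves
        # by SVD least squares and flags rank deficiency; the large-sparse
        # path tries LU first and falls back on any accuracy-check failure.
        flagged = False
        if n <= _DENSE_LIMIT:
            psi, _, rank, _ = np.linalg.lstsq(M.toarray(), b, rcond=None)
            flagged = rank < n
        else:
            psi = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                try:
                    psi = spla.spsolve(M.tocsc(), b)
                except RuntimeError:
                    psi = None
            ok = psi is not None and np.all(np.isfinite(psi)) \
                and np.abs(psi).max() < 1e10 \
                and abs(abs(psi[p_out]) ** 2 + abs(psi[p_in] - 1.0) ** 2 - 1.0) <= 1e-8
            if not ok:
                psi, _, rank, _ = np.linalg.lstsq(M.toarray(), b, rcond=None)
                flagged = rank < n

        r = psi[p_in] - 1.0
        t = psi[p_out]
        T, R = abs(t) ** 2, abs(r) ** 2
        return ScatteringResult(in_cell, out_cell, E, k, r, t, T, R,
                                abs(T + R - 1.0), flagged=flagged)

    # -- factorized all-pairs path ---------------------------------------

    def _cell_block_inverse(self, nodes: np.ndarray, E: float) -> np.ndarray | None:
        """Cell-block ``S`` of ``(H_comp - E I)^{-1}``; None if (near-)singular."""
        sub = self.H[nodes][:, nodes]
        n = len(nodes)
        cell_pos = np.flatnonzero(nodes < self.n_cells)
        A = sub - E * sp.identity(n, format="csr")
        rhs = np.zeros((n, len(cell_pos)))
        rhs[cell_pos, np.arange(len(cell_pos))] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            try:
                if n <= _DENSE_LIMIT:
                    X = scipy.linalg.solve(A.toarray(), rhs)
                else:
                    X = spla.splu(A.tocsc()).solve(rhs)
            except (np.linalg.LinAlgError, RuntimeError):
                return None
        if not np.all(np.isfinite(X)) or np.abs(X).max() > 1e10:
            return None
        probe = A @ X[:, :1] - rhs[:, :1]
        if np.abs(probe).max() > 1e-8:
            return None
        return X[cell_pos]

    def _singular_block_data(self, comp_id: int, E: float) -> tuple[np.ndarray, np.ndarray]:
        """Pseudoinverse cell-block and null-space cell rows at a singular E.

        When E is an eigenvalue of a component's H the interior operator
        ``A = H - E I`` has a null space.  Null vectors with no cell support
        ("dark states", living purely on virtual nodes) drop out of the pair
        closure; null vectors with cell support enter it as extra unknowns
        (see :meth:`_deflated_pair`).  Returns ``S`` (cell block of ``A^+``)
        and ``Ncell`` (cell rows of an orthonormal null basis, n_cells x q).
        The eigendecomposition is cached per component and reused across the
        (few) grid energies that hit the spectrum exactly.
        """
        if comp_id not in self._eig_cache:
            nodes = self._components[comp_id]
            sub = self.H[nodes][:, nodes].toarray()
            w, V = np.linalg.eigh(sub)
            cell_pos = np.flatnonzero(nodes < self.n_cells)
            self._eig_cache[comp_id] = (w, V, cell_pos)
        w, V, cell_pos = self._eig_cache[comp_id]
        d = w - E
        null_mask = np.abs(d) <= 1e-10
        inv = np.zeros_like(d)
        inv[~null_mask] = 1.0 / d[~null_mask]
        Vc = V[cell_pos]
        S = (Vc * inv) @ Vc.T
        Ncell = Vc[:, null_mask]
        return S, Ncell

    @staticmethod
    def _deflated_pair(S, Ncell, i, j, sigma, beta):
        """Bordered closure at a singular interior energy, one pair.

        Eliminating the range component of the interior operator leaves the
        2x2 lead closure augmented with one unknown per null direction that
        has support at the lead cells: with ``W = [N_i; N_j]`` (null-basis
        rows at the leads) the system is

            (I + sigma*C) w - W z = beta [S_ii, S_ij],
            sigma * W^T w         = beta  N_i,

        whose solution gives ``psi_IN, psi_OUT = w``.  Null directions with
        no weight at either lead decouple and are dropped.
        """
        a, bS, c = S[i, i], S[i, j], S[j, j]
        Wi, Wj = Ncell[i], Ncell[j]
        act = np.flatnonzero(np.abs(Wi) + np.abs(Wj) > 1e-12)
        if act.size == 0:
            det = (1 + sigma * a) * (1 + sigma * c) - sigma**2 * bS**2
            t = beta * bS / det
            r = beta * (a * (1 + sigma * c) - sigma * bS**2) / det - 1.0
            return r, t
        q = act.size
        K = np.zeros((2 + q, 2 + q), dtype=complex)
        K[0, 0] = 1 + sigma * a
        K[0, 1] = K[1, 0] = sigma * bS
        K[1, 1] = 1 + sigma * c
        K[0, 2:] = -Wi[act]
        K[1, 2:] = -Wj[act]
        K[2:, 0] = sigma * Wi[act]
        K[2:, 1] = sigma * Wj[act]
        rhs = np.zeros(2 + q, dtype=complex)
        rhs[0] = beta * a
        rhs[1] = beta * bS
        rhs[2:] = beta * Wi[act]
        y, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        return y[0] - 1.0, y[1]

    def all_pairs(self, E: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, R, flagged) over unordered cell pairs in triu order at one energy.

        Pair order matches ``numpy.triu_indices(n_cells, 1)``.  Numerically
        equal to looping :meth:`solve_pair`, but performs one factorization of
        the interior operator per connected component instead of one solve per
        pair.  Components for which the interior operator is singular (``E``
        an eigenvalue) transparently fall back to direct per-pair solves.
        """
        cfg = self.config
        nc = self.n_cells
        iu, ju = np.triu_indices(nc, k=1)
        T = np.zeros(iu.size)
        R = np.ones(iu.size)
        flagged = np.zeros(iu.size, dtype=bool)
        if _is_band_edge(E, cfg):
            if cfg.band_edge_policy == "skip":
                raise ValueError("band-edge energy with policy 'skip'")
            return T, R, flagged

        k = wavenumber_from_energy(E, cfg)
        sigma = np.exp(1j * k * cfg.a)
        beta = sigma - np.conj(sigma)
        # triu order is row-major: position = i*nc - i(i+1)/2 + (j - i - 1)
        def ppos(i, j):
            return i * nc - i * (i + 1) // 2 + (j - i - 1)

        for comp_id, nodes in enumerate(self._components):
            cells = nodes[nodes < nc]
            if cells.size < 2:
                continue
            S = self._cell_block_inverse(nodes, E)
            Ncell = None
            if S is None:  # E is an eigenvalue of this component's H
                S, Ncell = self._singular_block_data(comp_id, E)
            li, lj = np.triu_indices(cells.size, k=1)
            pos = ppos(cells[li], cells[lj])
            if Ncell is not None and Ncell.size and np.abs(Ncell).max() > 1e-10:
                # cell-supported null space at this energy: small components
                # use the (exact) direct bordered solves; large ones use the
                # deflated closure, whose accuracy is set by the eigenbasis
                if len(nodes) <= _DENSE_LIMIT:
                    for m, (i, j) in enumerate(zip(li, lj)):
                        res = self.solve_pair(int(cells[i]), int(cells[j]), E)
                        T[pos[m]], R[pos[m]] = res.T, res.R
                        flagged[pos[m]] = res.flagged
                    continue
                for m, (i, j) in enumerate(zip(li, lj)):
                    r, t = self._deflated_pair(S, Ncell, int(i), int(j), sigma, beta)
                    T[pos[m]] = abs(t) ** 2
                    R[pos[m]] = abs(r) ** 2
            else:
                a = S[li, li]
                c = S[lj, lj]
                b = S[li, lj]
                det = (1 + sigma * a) * (1 + sigma * c) - sigma**2 * b**2
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = beta * b / det
                    r = beta * (a * (1 + sigma * c) - sigma * b**2) / det - 1.0
                T[pos] = np.abs(t) ** 2
                R[pos] = np.abs(r) ** 2
            Tp, Rp = T[pos], R[pos]
            bad = (~np.isfinite(Tp)) | (~np.isfinite(Rp)) \
                | (np.abs(Tp + Rp - 1.0) > 1e-8)
            for m in np.flatnonzero(bad):
                res = self.solve_pair(int(cells[li[m]]), int(cells[lj[m]]), E)
                T[pos[m]], R[pos[m]] = res.T, res.R
                flagged[pos[m]] = res.flagged
        return T, R, flagged

    def wave_field(self, in_cell: int, out_cell: int, E: float) -> np.ndarray:
        """Node amplitudes ``|psi_m|^2`` over the whole circuit for one solve.

        Nodes outside the component of the endpoints carry no wave (zero).
        """
        res = self.solve_pair(in_cell, out_cell, E)
        # re-solve retaining the field (solve_pair discards it); diagnostic only
        cfg = self.config
        k = res.k
        psi = np.zeros(self.circuit.n_nodes, dtype=complex)
        if self._comp_of[in_cell] != self._comp_of[out_cell] or _is_band_edge(E, cfg):
            return np.abs(psi) ** 2
        nodes = self._components[self._comp_of[in_cell]]
        pos = {g: p for p, g in enumerate(nodes)}
        sub = self.H[nodes][:, nodes]
        sigma = np.exp(1j * k * cfg.a)
        diag = np.full(len(nodes), -E, dtype=complex)
        diag[pos[in_cell]] += sigma
        diag[pos[out_cell]] += sigma
        M = sub.astype(complex) + sp.diags(diag)
        b = np.zeros(len(nodes), dtype=complex)
        b[pos[in_cell]] = sigma - np.conj(sigma)
        psi[nodes] = scipy.linalg.solve(M.toarray(), b) if len(nodes) <= _DENSE_LIMIT \
            else spla.spsolve(M.tocsc(), b)
        return np.abs(psi) ** 2

    # -- spectra ----------------------------------------------------------

    def spectrum(self, E_grid: np.ndarray, method: str = "fast",
                 progress: bool = False) -> "TransmissionSpectrum":
        """Solve every unordered cell pair on every grid energy."""
        E_grid = np.asarray(E_grid, dtype=float)
        iu, ju = np.triu_indices(self.n_cells, k=1)
        T = np.zeros((iu.size, E_grid.size))
        R = np.zeros((iu.size, E_grid.size))
        flagged = np.zeros((iu.size, E_grid.size), dtype=bool)
        it = enumerate(E_grid)
        if progress:  # pragma: no cover - cosmetic
            try:
                from tqdm import tqdm

                it = tqdm(list(it), desc="energies")
            except ImportError:
                pass
        for col, E in it:
            if _is_band_edge(E, self.config) and self.config.band_edge_policy == "skip":
                T[:, col] = np.nan
                R[:, col] = np.nan
                continue
            if method == "fast":
                T[:, col], R[:, col], flagged[:, col] = self.all_pairs(E)
            elif method == "direct":
                for p, (i, j) in enumerate(zip(iu, ju)):
                    res = self.solve_pair(int(i), int(j), E)
                    if res is None:
                        continue
                    T[p, col], R[p, col] = res.T, res.R
                    flagged[p, col] = res.flagged
            else:
                raise ValueError("method must be 'fast' or 'direct'")
        return TransmissionSpectrum(E_grid=E_grid, pair_i=iu, pair_j=ju, T=T, R=R,
                                    corrected=np.zeros_like(flagged), flagged=flagged,
                                    n_cells=self.n_cells, config=self.config)


@dataclass
class TransmissionSpectrum:
    """Transmission/reflection of all unordered cell pairs over an energy grid.

    ``T`` and ``R`` have shape (n_pairs, n_energies) with pairs in
    ``numpy.triu_indices(n_cells, 1)`` order.
    """

    E_grid: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    T: np.ndarray
    R: np.ndarray
    corrected: np.ndarray
    flagged: np.ndarray
    n_cells: int
    config: ScatteringConfig = field(default_factory=ScatteringConfig)

    @property
    def n_pairs(self) -> int:
        return self.pair_i.size

    def mean_transmission(self) -> np.ndarray:
        """Pair-averaged transmission per grid energy."""
        if self.n_pairs == 0:
            raise ValueError("spectrum has no cell pairs")
        return self.T.mean(axis=0)

    def matrix_at(self, E: float, what: str = "T") -> np.ndarray:
        """Dense symmetric n_cells x n_cells coefficient matrix at grid energy E."""
        col = self._grid_index(E)
        vals = getattr(self, what)[:, col]
        m = np.zeros((self.n_cells, self.n_cells))
        m[self.pair_i, self.pair_j] = vals
        m[self.pair_j, self.pair_i] = vals
        return m

    def _grid_index(self, E: float) -> int:
        hit = np.flatnonzero(np.isclose(self.E_grid, E, atol=1e-9))
        if hit.size == 0:
            raise ValueError(f"energy {E} is not on the grid")
        return int(hit[0])

    def to_dataframe(self, names: list[str] | None = None):
        """Long-form DataFrame (pair_a, pair_b, E, T, R, corrected)."""
        import pandas as pd

        npair, ne = self.T.shape
        label = (lambda i: names[i]) if names else (lambda i: i)
        return pd.DataFrame({
            "pair_a": [label(int(i)) for i in np.repeat(self.pair_i, ne)],
            "pair_b": [label(int(j)) for j in np.repeat(self.pair_j, ne)],
            "E": np.tile(self.E_grid, npair),
            "T": self.T.ravel(),
            "R": self.R.ravel(),
            "corrected": self.corrected.ravel(),
        })

    def save_npz(self, path, config_hash: str = "") -> None:
        np.savez_compressed(
            path, E_grid=self.E_grid, pair_i=self.pair_i, pair_j=self.pair_j,
            T=self.T, R=self.R, corrected=self.corrected, flagged=self.flagged,
            n_cells=self.n_cells, config_hash=config_hash,
            gamma=self.config.gamma, a=self.config.a,
            conservation_tolerance=self.config.conservation_tolerance,
        )

    @classmethod
    def load_npz(cls, path) -> "TransmissionSpectrum":
        z = np.load(path, allow_pickle=False)
        cfg = ScatteringConfig(gamma=float(z["gamma"]), a=float(z["a"]),
                               conservation_tolerance=float(z["conservation_tolerance"]))
        return cls(E_grid=z["E_grid"], pair_i=z["pair_i"], pair_j=z["pair_j"],
                   T=z["T"], R=z["R"], corrected=z["corrected"], flagged=z["flagged"],
                   n_cells=int(z["n_cells"]), config=cfg)


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------

def solve_pair(circuit: CircuitGraph, in_cell: int, out_cell: int, E: float,
               cfg: ScatteringConfig | None = None) -> ScatteringResult | None:
    return TransmissionSolver(circuit, cfg).solve_pair(in_cell, out_cell, E)


def all_pairs_transmission(circuit: CircuitGraph, E: float,
                           cfg: ScatteringConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    T, R, _ = TransmissionSolver(circuit, cfg).all_pairs(E)
    return T, R


def compute_spectrum(circuit: CircuitGraph, E_grid: np.ndarray,
                     cfg: ScatteringConfig | None = None, method: str = "fast",
                     progress: bool = False) -> TransmissionSpectrum:
    return TransmissionSolver(circuit, cfg).spectrum(E_grid, method=method, progress=progress)


def conservation_policy(spectrum: TransmissionSpectrum,
                        tol: float | None = None) -> tuple[TransmissionSpectrum, dict]:
    """Post-correct conservation violations to (T, R) = (0, 1).

    Any entry with ``|T + R - 1| > tol`` is replaced by (0, 1) and flagged in
    ``corrected``; all others are untouched.  Returns the corrected spectrum
    (a copy) and a report with total and per-energy correction counts.
    """
    tol = spectrum.config.conservation_tolerance if tol is None else tol
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    bad = np.abs(spectrum.T + spectrum.R - 1.0) > tol
    T = spectrum.T.copy()
    R = spectrum.R.copy()
    T[bad] = 0.0
    R[bad] = 1.0
    out = replace(spectrum, T=T, R=R, corrected=bad.copy())
    per_energy = bad.sum(axis=0)
    report = {
        "n_corrected": int(bad.sum()),
        "per_energy": {float(E): int(c) for E, c in zip(spectrum.E_grid, per_energy) if c},
    }
    return out, report


def gamma_sweep(circuit: CircuitGraph, gammas=(1.0, 2.5, 5.0, 10.0),
                n_k: int = 100, a: float = 1.0) -> dict[float, dict[str, np.ndarray]]:
    """Pair-averaged transmission on k-uniform grids for several gamma values.

    For each gamma, ``n_k`` equally spaced wavenumbers on [0, pi/a] are mapped
    to energies spanning the band [-2*gamma, 2*gamma] (non-uniform in E), and
    the all-pairs mean transmission is evaluated at each.  Returns
    ``{gamma: {"k": ..., "E": ..., "mean_T": ...}}``.
    """
    if n_k < 2:
        raise ValueError("n_k must be at least 2")
    out: dict[float, dict[str, np.ndarray]] = {}
    for g in gammas:
        if g <= 0:
            raise ValueError("gamma values must be positive")
        cfg = ScatteringConfig(gamma=float(g), a=a)
        solver = TransmissionSolver(circuit, cfg)
        ks = np.linspace(0.0, math.pi / a, n_k)
        Es = 2.0 * g * np.cos(ks * a)
        mean_T = np.empty(n_k)
        for m, E in enumerate(Es):
            T, _, _ = solver.all_pairs(float(E))
            mean_T[m] = T.mean() if T.size else 0.0
        out[float(g)] = {"k": ks, "E": Es, "mean_T": mean_T}
    return out
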
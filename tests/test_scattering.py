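"""Scattering solves: dispersion, closed forms, conservation, fast path."""

import math

import numpy as np
import pytest

import gapwave.scattering as sc
from gapwave.circuit_model import build_circuit
from gapwave.network_io import synthetic_chain, synthetic_random

from conftest import dense_bordered_solve, make_net


CFG = sc.ScatteringConfig()


# ---------------------------------------------------------------------------
# dispersion and grids
# ---------------------------------------------------------------------------

def test_dispersion_relation():
    assert sc.energy_from_wavenumber(math.pi / 2, CFG) == pytest.approx(0.0, abs=1e-12)
    assert sc.energy_from_wavenumber(0.0, CFG) == pytest.approx(10.0)
    k = sc.wavenumber_from_energy(0.225, CFG)
    assert k == pytest.approx(math.acos(0.0225), abs=1e-14)
    assert sc.energy_from_wavenumber(k, CFG) == pytest.approx(0.225, abs=1e-12)
    with pytest.raises(ValueError):
        sc.wavenumber_from_energy(10.5, CFG)


def test_energy_grid_defaults_and_bounds():
    grid = sc.make_energy_grid()
    assert grid.size == 801
    assert grid[0] == -10.0 and grid[-1] == 10.0
    assert np.allclose(np.diff(grid), 0.025)
    small = sc.make_energy_grid(-5, 5, 0.1, sc.ScatteringConfig(gamma=2.5))
    assert small.size == 101
    with pytest.raises(ValueError, match="band"):
        sc.make_energy_grid(-11, 11, 0.025)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("w", np.arange(0.1, 1.01, 0.1))
def test_single_junction_closed_form(w):
    """One junction at E=0 transmits T = 4w^2 / (w^2+1)^2.

    Oracle: hand elimination of the 4-unknown bordered system, cross-checked
    against an independently assembled dense solve.
    """
    g = 40.0 * w  # anatomical weight giving hop weight w
    net = make_net(["A", "B"], [("A", "B", g)])
    res = sc.solve_pair(build_circuit(net), 0, 1, 0.0)
    expected_T = 4 * w**2 / (w**2 + 1) ** 2
    assert res.T == pytest.approx(expected_T, abs=1e-10)
    assert res.R == pytest.approx(1 - expected_T, abs=1e-10)
    r_o, t_o = dense_bordered_solve(net, 0, 1, 0.0)
    assert abs(res.t - t_o) < 1e-12 and abs(res.r - r_o) < 1e-12


def test_half_weight_values():
    net = make_net(["A", "B"], [("A", "B", 20.0)])
    res = sc.solve_pair(build_circuit(net), 0, 1, 0.0)
    assert res.T == pytest.approx(0.64, abs=1e-10)
    assert res.R == pytest.approx(0.36, abs=1e-10)


def test_perfect_junction_transmits_fully():
    net = make_net(["A", "B"], [("A", "B", 40.0)])
    res = sc.solve_pair(build_circuit(net), 0, 1, 0.0)
    assert res.T == pytest.approx(1.0, abs=1e-10)
    assert res.R == pytest.approx(0.0, abs=1e-10)


def test_disconnected_pair_reflects_everything():
    net = make_net(["A", "B", "C"], [("A", "B", 40.0)])
    res = sc.solve_pair(build_circuit(net), 0, 2, 1.7)
    assert res.T == 0.0 and res.R == 1.0


def test_deleting_only_path_kills_transmission():
    chain = synthetic_chain(4, 40.0)
    cut = make_net([c.name for c in chain.cells],
                   [("A0", "A1", 40.0), ("A2", "A3", 40.0)])  # middle edge removed
    solver = sc.TransmissionSolver(build_circuit(cut))
    for E in np.linspace(-9.5, 9.5, 21):
        res = solver.solve_pair(0, 3, float(E))
        assert res.T == 0.0 and res.R == 1.0


# ---------------------------------------------------------------------------
# conservation, reciprocity, oracle equivalence
# ---------------------------------------------------------------------------

def test_conservation_and_reciprocity_small_networks():
    rng = np.random.default_rng(0)
    energies = np.linspace(-9.5, 9.5, 7)
    for seed in range(8):
        net = synthetic_random(10, 18, seed=seed)
        solver = sc.TransmissionSolver(build_circuit(net))
        for E in energies:
            for _ in range(3):
                i, j = rng.choice(10, size=2, replace=False)
                fwd = solver.solve_pair(int(i), int(j), float(E))
                bwd = solver.solve_pair(int(j), int(i), float(E))
                assert fwd.conservation_error <= 1e-8
                assert abs(fwd.T - bwd.T) <= 1e-10


def test_fast_path_matches_direct(random_net_factory):
    for seed in range(5):
        net = random_net_factory(seed, n_cells=9)
        solver = sc.TransmissionSolver(build_circuit(net))
        for E in (-3.3, -0.375, 0.0, 0.225, 1.0, 4.8):
            T, R, _ = solver.all_pairs(E)
            iu, ju = np.triu_indices(9, k=1)
            for p, (i, j) in enumerate(zip(iu, ju)):
                res = solver.solve_pair(int(i), int(j), E)
                assert abs(T[p] - res.T) <= 1e-10
                assert abs(R[p] - res.R) <= 1e-10


def test_fast_path_at_interior_eigenvalue():
    """E=0 is an eigenvalue of the interior operator when isolated cells exist;
    the fast path must still agree with the direct solves."""
    net = make_net(["A", "B", "C"], [("A", "B", 20.0)])  # C isolated
    solver = sc.TransmissionSolver(build_circuit(net))
    T, R, _ = solver.all_pairs(0.0)
    assert T[0] == pytest.approx(0.64, abs=1e-10)  # pair (A, B)
    assert T[1] == 0.0 and R[1] == 1.0             # pair (A, C) disconnected


def test_deflated_closure_matches_direct_at_singular_energy():
    """The large-component closure for energies hitting the interior spectrum
    (extra unknowns for cell-supported null directions) reproduces the direct
    bordered solves to its documented accuracy."""
    net = synthetic_random(13, 20, seed=104)  # E=0 is an eigenvalue w/ cell support
    solver = sc.TransmissionSolver(build_circuit(net))
    comp = solver._comp_of[0]
    S, Ncell = solver._singular_block_data(comp, 0.0)
    assert Ncell.shape[1] >= 1 and np.abs(Ncell).max() > 1e-10
    nodes = solver._components[comp]
    cells = nodes[nodes < 13]
    local = {int(g): p for p, g in enumerate(cells)}
    sigma = np.exp(1j * np.pi / 2)
    beta = sigma - np.conj(sigma)
    for gi, gj in [(0, 1), (4, 10), (3, 11), (2, 7)]:
        r, t = solver._deflated_pair(S, Ncell, local[gi], local[gj], sigma, beta)
        res = solver.solve_pair(gi, gj, 0.0)
        assert abs(abs(t) ** 2 - res.T) < 1e-8
        assert abs(abs(r) ** 2 - res.R) < 1e-8


def test_wave_field_consistent_with_amplitudes(single_edge_half):
    solver = sc.TransmissionSolver(build_circuit(single_edge_half))
    res = solver.solve_pair(0, 1, 0.0)
    m = solver.wave_field(0, 1, 0.0)
    assert m[0] == pytest.approx(abs(1 + res.r) ** 2, abs=1e-12)
    assert m[1] == pytest.approx(res.T, abs=1e-12)


# ---------------------------------------------------------------------------
# band edge and conservation policy
# ---------------------------------------------------------------------------

def test_band_edge_policy(single_edge_half):
    circuit = build_circuit(single_edge_half)
    res = sc.solve_pair(circuit, 0, 1, 10.0)
    assert res.T == 0.0 and res.R == 1.0
    skip_cfg = sc.ScatteringConfig(band_edge_policy="skip")
    assert sc.solve_pair(circuit, 0, 1, -10.0, skip_cfg) is None


def test_conservation_policy_rules(single_edge_half):
    spec = sc.compute_spectrum(build_circuit(single_edge_half), np.array([0.0, 1.0, 2.0]))
    # inject violations: one slight (within tol), one gross
    spec.T[0, 1] = spec.T[0, 1] + 1e-6
    spec.T[0, 2] = 0.7
    spec.R[0, 2] = 0.301
    fixed, report = sc.conservation_policy(spec, tol=1e-5)
    assert not fixed.corrected[0, 0] and not fixed.corrected[0, 1]
    assert fixed.corrected[0, 2]
    assert fixed.T[0, 2] == 0.0 and fixed.R[0, 2] == 1.0
    assert fixed.T[0, 1] == spec.T[0, 1]  # within tolerance: untouched
    assert report["n_corrected"] == 1
    assert report["per_energy"] == {2.0: 1}


# ---------------------------------------------------------------------------
# gamma sweep
# ---------------------------------------------------------------------------

def test_gamma_sweep_grids_and_midband_agreement():
    circuit = build_circuit(synthetic_chain(3, 20.0))
    curves = sc.gamma_sweep(circuit, gammas=(1.0, 2.5, 5.0), n_k=9)
    for g, c in curves.items():
        assert c["E"].max() == pytest.approx(2 * g)
        assert c["E"].min() == pytest.approx(-2 * g)
        assert c["k"].size == 9
    # at E=0 (k=pi/2) the solve is gamma-independent: the bordered system
    # depends on gamma only through k, and k(E=0)=pi/2 for every gamma
    mids = [c["mean_T"][4] for c in curves.values()]  # middle k = pi/2
    assert np.ptp(mids) < 1e-12


def test_gamma_sweep_hundred_points():
    circuit = build_circuit(make_net(["A", "B"], [("A", "B", 40.0)]))
    curves = sc.gamma_sweep(circuit, gammas=(2.5,), n_k=100)
    assert curves[2.5]["mean_T"].size == 100
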
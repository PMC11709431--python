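"""Transmission-curve statistics: mobility edge, maps, hubs, distances."""

import math

import numpy as np
import pytest

import gapwave.wdtm_analysis as wa
from gapwave.circuit_model import build_circuit
from gapwave.network_io import synthetic_chain, synthetic_random
from gapwave.scattering import ScatteringConfig, TransmissionSpectrum, compute_spectrum

from conftest import make_net


def make_spectrum(n_cells, E_grid, T):
    """Assemble a spectrum container directly from a (n_pairs, n_E) T array."""
    iu, ju = np.triu_indices(n_cells, k=1)
    T = np.asarray(T, dtype=float)
    return TransmissionSpectrum(
        E_grid=np.asarray(E_grid, dtype=float), pair_i=iu, pair_j=ju,
        T=T, R=1 - T, corrected=np.zeros(T.shape, bool),
        flagged=np.zeros(T.shape, bool), n_cells=n_cells,
        config=ScatteringConfig())


# ---------------------------------------------------------------------------
# average transmission
# ---------------------------------------------------------------------------

def test_average_all_ones():
    spec = make_spectrum(3, [0.0, 1.0], np.ones((3, 2)))
    assert np.all(wa.average_transmission(spec).mean_T == 1.0)


def test_average_single_weak_pair_below_reference():
    """One pair at 1% among ~1e5 silent pairs averages below the 1e-7 level."""
    n_cells = 469  # 109,746 pairs
    n_pairs = n_cells * (n_cells - 1) // 2
    T = np.zeros((n_pairs, 1))
    T[0, 0] = 0.01
    spec = make_spectrum(n_cells, [0.0], T)
    mean = wa.average_transmission(spec).mean_T[0]
    assert mean == pytest.approx(0.01 / n_pairs)
    assert mean < 1e-7


def test_average_empty_pairs_error():
    spec = make_spectrum(1, [0.0], np.zeros((0, 1)))
    with pytest.raises(ValueError):
        wa.average_transmission(spec)


# ---------------------------------------------------------------------------
# mobility edge
# ---------------------------------------------------------------------------

def test_mobility_edge_on_step_curve():
    E = np.arange(-10, 10.01, 0.5)
    y = np.where(np.abs(E) <= 3.0, 1.0, 0.0)
    curve = wa.TransmissionCurve(E, y)
    edge = wa.find_mobility_edge(curve, threshold=1e-7)
    assert edge == (-3.5, 3.5)  # first grid points past +-3


def test_mobility_edge_absent_when_curve_never_vanishes():
    E = np.arange(-10, 10.01, 0.5)
    curve = wa.TransmissionCurve(E, np.ones_like(E))
    assert wa.find_mobility_edge(curve) is None


def test_mobility_edge_persistence_skips_isolated_peaks():
    """An isolated resonance inside the decayed tail pushes the edge outward."""
    E = np.arange(-10, 10.01, 0.5)
    y = np.where(np.abs(E) <= 3.0, 1.0, 0.0)
    y[np.flatnonzero(E == 6.0)[0]] = 1e-3  # lone peak beyond the step
    edge = wa.find_mobility_edge(wa.TransmissionCurve(E, y), threshold=1e-7)
    assert edge == (-3.5, 6.5)


# ---------------------------------------------------------------------------
# strong pairs / WDTM
# ---------------------------------------------------------------------------

def test_strong_pairs_strict_inequality():
    spec = make_spectrum(3, [0.0], np.full((3, 1), 0.5))
    assert wa.strong_pairs(spec, 0.0).pairs == []  # T == cutoff excluded


def test_strong_pairs_from_half_weight_junction():
    net = make_net(["A", "B"], [("A", "B", 20.0)])
    spec = compute_spectrum(build_circuit(net), np.array([0.0]))
    wdtm = wa.strong_pairs(spec, 0.0)
    assert wdtm.pairs == [(0, 1)]
    assert wdtm.T[(0, 1)] == pytest.approx(0.64, abs=1e-10)


def test_strong_pairs_zero_cutoff_takes_all_transmitting():
    spec = make_spectrum(3, [0.0], np.array([[0.2], [0.0], [0.9]]))
    assert wa.strong_pairs(spec, 0.0, cutoff=0.0).pairs == [(0, 1), (1, 2)]


def test_strong_pairs_off_grid_energy_error():
    spec = make_spectrum(3, [0.0], np.zeros((3, 1)))
    with pytest.raises(ValueError, match="grid"):
        wa.strong_pairs(spec, 0.3)


# ---------------------------------------------------------------------------
# energy selection
# ---------------------------------------------------------------------------

def test_select_energies_monotone_curve_empty():
    E = np.linspace(-2, 2, 9)
    spec = make_spectrum(3, E, np.full((3, 9), 0.9))
    curve = wa.TransmissionCurve(E, np.linspace(0, 1, 9))
    assert wa.select_wdtm_energies(curve, spec) == []


def test_select_energies_positive_peaks_only():
    E = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y = np.array([0.1, 0.9, 0.1, 0.9, 0.1])  # symmetric peaks at +-1
    T = np.full((3, 5), 0.6)
    spec = make_spectrum(3, E, T)
    assert wa.select_wdtm_energies(wa.TransmissionCurve(E, y), spec) == [1.0]


def test_select_energies_requires_strong_pair():
    E = np.array([0.5, 1.0, 1.5])
    y = np.array([0.1, 0.4, 0.1])
    spec = make_spectrum(3, E, np.full((3, 3), 0.4))  # nothing above 0.5
    assert wa.select_wdtm_energies(wa.TransmissionCurve(E, y), spec) == []


def test_select_energies_plateau_counts_once_at_left_edge():
    E = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
    y = np.array([0.1, 0.8, 0.8, 0.1, 0.1])
    spec = make_spectrum(3, E, np.full((3, 5), 0.7))
    assert wa.select_wdtm_energies(wa.TransmissionCurve(E, y), spec) == [1.0]


# ---------------------------------------------------------------------------
# appearance rate and hubs
# ---------------------------------------------------------------------------

def test_appearance_rate_extremes():
    m = 31
    E = np.arange(m, dtype=float)
    T = np.zeros((3, m))
    T[0, :] = 0.9          # present in all maps
    T[1, 0] = 0.7          # present once
    spec = make_spectrum(3, E, T)
    rates = wa.appearance_rate(spec, list(E))
    assert rates.rate[0] == 1.0
    assert rates.rate[1] == pytest.approx(1 / 31)
    assert rates.rate[2] == 0.0
    # every rate is an exact multiple of 1/m
    assert np.allclose(np.round(rates.rate * m), rates.rate * m, atol=0)


def test_appearance_counts_exact_cutoff_but_wdtm_excludes_it():
    """theta[0] = 1: T == 0.5 counts as an appearance even though the map
    itself keeps only strict T > 0.5."""
    spec = make_spectrum(2, [0.0], np.array([[0.5]]))
    assert wa.strong_pairs(spec, 0.0).pairs == []
    assert wa.appearance_rate(spec, [0.0]).rate[0] == 1.0


def test_appearance_rate_needs_energies():
    spec = make_spectrum(2, [0.0], np.array([[0.5]]))
    with pytest.raises(ValueError):
        wa.appearance_rate(spec, [])


def test_find_hubs_threshold_and_order():
    rates = wa.AppearanceRateMatrix(
        energies=[0.1], pair_i=np.array([0, 0, 1]), pair_j=np.array([1, 2, 2]),
        rate=np.array([0.23, 0.10, 0.03]), n_cells=3)
    hubs = wa.find_hubs(rates, 0.1, names=["X", "Y", "Z"])
    assert [(h["name_a"], h["name_b"]) for h in hubs] == [("X", "Y"), ("X", "Z")]
    assert wa.find_hubs(rates, 1.0) == []
    with pytest.raises(ValueError):
        wa.find_hubs(rates, 0.0)


# ---------------------------------------------------------------------------
# distances and strand patterns
# ---------------------------------------------------------------------------

def test_pair_distance_basics():
    chain = synthetic_chain(5, 40.0)
    assert wa.pair_distance(chain, 0, 1) == 1
    assert wa.pair_distance(chain, 2, 2) == 0
    assert wa.pair_distance(chain, 0, 4) == 4
    split = make_net("ABC", [("A", "B", 1.0)])
    assert wa.pair_distance(split, 0, 2) == math.inf


def test_pair_distance_triangle_inequality():
    rng = np.random.default_rng(5)
    net = synthetic_random(10, 20, seed=2)
    for _ in range(30):
        i, j, k = rng.choice(10, size=3, replace=False)
        dij = wa.pair_distance(net, int(i), int(j))
        djk = wa.pair_distance(net, int(j), int(k))
        dik = wa.pair_distance(net, int(i), int(k))
        if math.isfinite(dij) and math.isfinite(djk):
            assert dik <= dij + djk


@pytest.mark.parametrize("dists,gcd,nontrivial", [
    ([2, 4, 6], 2, True),
    ([3, 6, 9], 3, True),
    ([2, 3], 1, False),
])
def test_strand_pattern_gcd(dists, gcd, nontrivial):
    chain = synthetic_chain(12, 40.0)
    pairs = [(0, d) for d in dists]
    wdtm = wa.WDTM(E=1.0, cutoff=0.5, pairs=pairs, T={p: 0.8 for p in pairs})
    (report,) = wa.strand_pattern(wdtm, chain, {"s1": list(range(12))})
    assert report.distances == sorted(dists)
    assert report.gcd == gcd
    assert report.all_multiples
    assert report.nontrivial is nontrivial


def test_strand_pattern_ignores_extra_strand_pairs():
    chain = synthetic_chain(12, 40.0)
    wdtm = wa.WDTM(E=1.0, cutoff=0.5, pairs=[(0, 4), (0, 11)], T={})
    reports = wa.strand_pattern(wdtm, chain, {"low": list(range(6)), "high": list(range(6, 12))})
    by_name = {r.strand: r for r in reports}
    assert by_name["low"].distances == [4]
    assert by_name["high"].distances == []
    assert by_name["high"].gcd is None
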
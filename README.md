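# gapwave

Wave scattering and effective-conductance analysis of gap-junction
(electrical-synapse) networks.

## The problem

Cells coupled by gap junctions exchange subthreshold membrane-potential
oscillations directly and bidirectionally. When such an oscillation
propagates through a network it takes every available path at once, and the
paths interfere: constructively at some wavelengths, destructively at
others. `gapwave` models this by mapping a weighted gap-junction network
(such as the 469-cell, 1433-junction hermaphrodite *C. elegans* connectome)
onto a tight-binding scattering circuit and computing, for every cell pair
and every wavenumber, how much of an injected sinusoidal wave is
transmitted. It is aimed at researchers studying synchronized rhythmic
activity on electrically coupled networks who want an interference-aware
alternative to plain resistor-network (effective conductance) reasoning.

## The model

Each junction between cells *i* and *j* with anatomical weight `g_ij` is
expanded into a Cell–VN–VN–Cell segment of two virtual nodes. Cell-to-VN
hops carry amplitude 1; the central VN–VN hop carries the processed weight
`w_ij = min(1, g_ij / 40)`. With on-site energies set to zero (the common
resting potential), the circuit's hopping matrix is a tight-binding Anderson
Hamiltonian `H`; for the full connectome it is 3335 × 3335
(469 cells + 2 × 1433 virtual nodes).

A wave with wavenumber `k` (energy `E = 2γ cos ka`, default `γ = 5`,
`a = 1`) is injected at an IN cell and detected at an OUT cell through
perfect leads. Writing `ψ_IN = 1 + r` and `ψ_OUT = t`, the stationary
condition reduces to a bordered complex linear system whose solution gives
the reflection and transmission coefficients `R = |r|²`, `T = |t|²` with
`T + R = 1` (the circuit is lossless). An all-pairs fast path factorizes the
pair-independent interior operator `H − E·I` once per energy and closes each
pair with a 2 × 2 Schur complement, so the full 109,746-pair sweep costs one
factorization plus O(1) work per pair.

Downstream, the package computes the pair-averaged spectrum `⟨T(E)⟩`, the
signal mobility edge (where `⟨T⟩` falls below 10⁻⁷ for good), the
wavenumber-dependent transmission maps (WDTMs: pairs with `T > 0.5` at
selected peak energies), appearance-rate hub statistics across the selected
energies, shortest-path distance patterns along muscle strands, and — as the
no-interference baseline — the all-pairs effective conductance
`G_eff = 1/R_eff` of the resistor network with `ω_ij = g_ij`, via the
Laplacian pseudoinverse.

## Worked example

```python
import numpy as np
import gapwave as gw
from gapwave import wdtm_analysis as wa, conductance as cond

# two muscle strands of 8 cells each, one hub cell on both strand necks
net = gw.generate_synthetic("strand_bundle", n_strands=2, strand_len=8)
print(net.n_cells, net.n_edges)            # 17 18

circuit = gw.build_circuit(net)
solver = gw.TransmissionSolver(circuit, gw.ScatteringConfig(gamma=5.0))

res = solver.solve_pair(0, 1, E=0.0)       # adjacent muscles, band centre
print(round(res.T, 3), round(res.R, 3))    # 0.985 0.015

spec = solver.spectrum(gw.make_energy_grid(-10, 10, 0.5))
spec, report = gw.conservation_policy(spec)
curve = wa.average_transmission(spec)
print(round(curve.mean_T.max(), 3))        # 0.733
print(wa.find_mobility_edge(curve, 1e-7))  # (-7.0, 7.0)

energies = wa.select_wdtm_energies(curve, spec)
print(energies)                            # [0.5, 1.5]

G = cond.all_pairs_conductance(net).G      # interference-free baseline
print(round(G[0, 1], 1))                   # 100.0  (single 100-unit junction)
```

The transmission numbers are interference products: the adjacent muscles
sit on a saturated hop (`w = 1`) but lose 1.5% to back-scattering off the
rest of the strand, the bundle transmits strongly over a broad mid-band
region (peak mean T ≈ 0.73 on this coarse grid) and goes quiet beyond ±7,
and the map energies pick out the peaks of the landscape. The conductance
baseline, by contrast, sees only the resistor value.

A `gapwave` CLI mirrors the library (`ingest`, `simulate`, `transmit`,
`conductance`, `analyze`, `report`); `gapwave report --config run.yaml` runs
the full pipeline and writes every table, the spectrum cache and a manifest
stamped with the config hash.

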
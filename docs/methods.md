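# Methods

## Circuit model

A gap-junction network is an undirected weighted graph: cells are nodes,
junctions are edges, and the anatomical weight `g_ij > 0` is proportional to
the structural size of the junction (integers 1–401 in the reference
hermaphrodite connectome, heavy-tailed). The scattering circuit expands
each junction into a Cell–VN–VN–Cell segment with two virtual nodes (VNs):
the cell-to-VN hops stand for the intracellular conductors and carry hopping
amplitude 1, while the central VN–VN hop stands for the junction itself and
carries the processed weight

    w_ij = min(1, g_ij / 40),

so a junction of anatomical weight ≥ 40 is a perfect transmitter across that
hop and smaller junctions transmit proportionally. All hops share one
nominal length `a`, and on-site energies are zero: the resting membrane
potential, common to all cells, is the energy reference. The hopping matrix
of the circuit is a real symmetric tight-binding (Anderson) Hamiltonian `H`
of dimension `n_cells + 2·n_edges` — 3335 for the 469-cell / 1433-junction
connectome. Virtual-node indices follow input edge order (`n_cells + 2e`,
`n_cells + 2e + 1` for edge rank `e`), making the matrix bit-reproducible
from a given edge list.

The model deliberately omits attenuation (the circuit is lossless, so
`T + R = 1` exactly), voltage gating, rectifying junctions, membrane
capacitance, and chemical synapses.

## Scattering calculation

A monochromatic wave of wavenumber `k ∈ [0, π/a]` has energy
`E = 2γ cos(ka)`; valid energies fill the band `[−2γ, 2γ]`. `γ` is the
lead coupling scale; the default `γ = 5` gives the band `[−10, 10]`, wide
enough to exhibit the transmission cut-off while keeping a uniform energy
grid reasonably dense in `k`. `a` is a pure convention and is fixed at 1,
so wavenumbers are reported in radians per edge. The `gamma_sweep` helper
reproduces the calibration view (γ ∈ {1, 2.5, 5, 10}, 100 k-uniform
samples each): the transmission landscape is a function of `E` essentially
independent of γ, which only stretches the band.

An injector lead drives the IN cell with a unit-amplitude, zero-phase wave
and collects the reflected wave `r`; a detector lead collects the
transmitted wave `t` at the OUT cell. With `ψ_IN = 1 + r`, `ψ_OUT = t` and
lead phases `e^{±ika}` over the lead length `a`, the stationary condition
`Hψ + φ_leads = Eψ` becomes a bordered complex linear system: interior rows
`(H − E·I)ψ = 0`, lead rows augmented by `e^{ika}` on the diagonal, and the
single source entry `e^{ika} − e^{−ika} = 2i·sin(ka)` on the IN row. Then
`T = |t|²`, `R = |r|²`.

### Fast all-pairs path

The lead self-energies are a rank-2 diagonal update of the pair-independent
interior operator `A = H − E·I`. With `S` the cell-block of `A⁻¹`,
`σ = e^{ika}` and `β = 2i·sin(ka)`, eliminating the interior nodes leaves

    (I₂ + σC) [ψ_IN, ψ_OUT]ᵀ = β [S_ii, S_ij]ᵀ,   C = [[S_ii, S_ij], [S_ij, S_jj]],

i.e. `t = β·S_ij/det` and `r = β(S_ii(1 + σS_jj) − σS_ij²)/det − 1` with
`det = (1 + σS_ii)(1 + σS_jj) − σ²S_ij²`. One factorization of `A` per
energy (per connected component) plus `n_cells` triangular solves therefore
serves all ~10⁵ pairs, at roughly one second per energy for the full
connectome on one CPU. Components are handled separately; cross-component
pairs are exactly `T = 0, R = 1` (the same closure yields `|r| = 1`
identically when `S_ij = 0`). The fast path is verified against the direct
per-pair solver to 10⁻¹⁰ in the test suite.

### Singular energies and numerical guards

When a grid energy coincides with an eigenvalue of a component's `H`, the
interior operator is exactly singular. Eigenvectors with no weight on any
cell ("dark states", supported on virtual nodes only) are invisible to the
leads: the closure above remains valid with `S` taken from the
pseudoinverse. Eigenvectors with cell support enter the closure as extra
unknowns; the deflated system

    (I₂ + σC) w − W z = β[S_ii, S_ij]ᵀ,    σ Wᵀ w = β N_i,

(`N` = null-basis cell rows, `W` its IN/OUT rows) recovers the physical
solution. In the direct solver the same situation makes the bordered matrix
rank-deficient with null vectors that vanish on the leads, so the
minimum-norm least-squares solution is the physical one (it equals the
limit of nearby energies); a plain LU solve would silently add an arbitrary
null component that can look unitary while being wrong. Consequently the
dense direct path always solves by SVD least squares and flags rank
deficiency, components up to 600 nodes delegate singular energies to those
exact direct solves, and larger components use the deflated closure (whose
accuracy, set by the eigenbasis, is ~10⁻⁸). Any pair failing the
conservation check `|T + R − 1| ≤ 10⁻⁸` after the fast closure is re-solved
directly.

Independently of these guards, the published post-correction policy is
applied to final spectra: any entry violating `|T + R − 1| ≤ 10⁻⁵` is
replaced by `(T, R) = (0, 1)`, flagged, and counted per energy in the run
report.

### Band edges

At `|E| = 2γ` the incident flux `2i·sin(ka)` vanishes and the scattering
problem degenerates. The default policy defines `T = 0, R = 1` there
without solving (consistent with the vanishing transmission approaching the
edges); a `skip` policy excludes those grid points instead. The default
energy grid is `[−10, 10]` in steps of 0.025 — 801 points.

## Downstream statistics

* **Mean curve** `⟨T(E)⟩`: arithmetic mean over all unordered pairs,
  post-correction.
* **Mobility edge**: the smallest positive (and symmetric negative) grid
  energy beyond which `⟨T⟩ ≤ 10⁻⁷` *persistently* (every grid point
  outward). Persistence, rather than first crossing, makes the edge robust
  to isolated resonant peaks in the localized tail. The 10⁻⁷ reference is
  roughly one pair in 10⁵ transmitting at 1%.
* **WDTM**: the set of pairs with `T(E) > 0.5` (strict) at one energy.
  Energies are selected by three criteria: local maximum of the mean curve
  (strictly above both neighbours; a plateau counts once at its leftmost
  point if it dominates both flanks), at least one pair above the cutoff,
  and `E > 0` (the curve is symmetric, negative peaks are redundant).
* **Appearance rate**: per pair, the mean of the step statistic
  `θ[T(E) − 0.5]` over the selected energies with `θ[0] = 1`, so every rate
  is an exact multiple of `1/m`. The boundary case `T = 0.5` counts as an
  appearance although WDTM membership is strict; the disagreement is
  measure-zero and covered by an explicit test. Hub pairs are those with
  rate ≥ 3/m (exposed as a parameter), sorted by rate then name.
* **Distances**: unweighted shortest-path lengths on the cell graph
  (virtual nodes excluded), `∞` across components. Strand pattern reports
  restrict a WDTM to intra-strand pairs (strand membership is supplied as
  metadata, not inferred) and give the gcd of the distance multiset.

## Effective-conductance baseline

The no-interference comparison treats each junction as a resistor of
conductance `ω_ij = g_ij` — the *raw* anatomical weight, intentionally not
the processed `w_ij`, so the two models answer the same question with and
without interference on their own natural scales (units are arbitrary).
Effective resistance comes from the weighted Laplacian pseudoinverse,
`R_eff(i,j) = L⁺_ii + L⁺_jj − 2L⁺_ij`, computed block-wise per connected
component so that cross-component pairs are exactly `G_eff = 0` rather than
numeric overflow; one pseudoinverse serves all pairs. Voltage profiles are
checked against Kirchhoff's current law, and Rayleigh monotonicity (adding
a resistor never lowers any conductance) is verified numerically.

## Synthetic networks

The generator provides `chain`, `ring`, `strand_bundle`, `random` and the
composite `connectome` topology used as the connectome-scale study fixture.
It emulates the anatomical motifs of the hermaphrodite gap-junction
network: four linear body-wall muscle strands of 24 cells, one hub cell
(named `hmc` after the head mesodermal cell) strongly attached (weight 300)
to the seventh and eighth muscle of every strand, and a dense random core
over the remaining 372 cells with log-uniform integer weights on [1, 401]
(matching the observed heavy-tailed range), for exactly 469 cells and 1433
edges. All generators are bit-reproducible under a fixed seed.

What the fixture does *not* emulate: the real connectome's cell identities
and type-specific wiring (named neuron classes, left/right homologues, the
pharyngeal circuit), its degree correlations, and inter-strand muscle
wiring. Tests passing on synthetic networks therefore validate the
machinery and its invariants — counts, conservation, reciprocity, oracle
equivalence, statistic definitions — not the biological map itself; runs on
the real adjacency workbook (via `read_connectome_workbook` or the CLI
`ingest`) are needed for cell-level conclusions.

## Numerical choices

* Dense LAPACK solves for systems up to 600 nodes, sparse LU above; the
  threshold trades factorization overhead against fill-in and is not
  load-bearing for correctness.
* Conservation accuracy target 10⁻⁸ internally (guard), 10⁻⁵ for the
  published post-correction policy.
* Null-space detection threshold 10⁻¹⁰ on `|λ − E|`; lead-support threshold
  10⁻¹² on null-basis rows.
* Test problem sizes (coarse grids of ΔE = 0.25–0.5, networks of 9–50
  cells, one connectome-scale run at ΔE = 0.5) were chosen to keep the
  default suite around a minute while still crossing every code path,
  including singular energies; the physics is scale-free in the grid, so a
  finer grid only adds resolution, not new regimes.

## Known limitations

* Exact recovery of a specific published count of selected map energies
  depends on grid resolution and plateau handling; the selection criteria
  are implemented as stated and the plateau rule is documented above and
  configurable.
* The deflated closure at singular energies in very large components is
  accurate to ~10⁻⁸, not machine precision.
* Heterogeneous on-site energies (disorder), AC impedance and time-domain
  propagation are out of scope.
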
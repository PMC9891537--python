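# Methods

## The model family

All models are deterministic mass-action ODE systems over continuous
per-cell molecule counts; time is in hours.  A cell carries ligand monomer
`L`, ligand dimer (or size-`n` oligomer) `L*`, receptor `N` and free
intracellular domain `S`; `S` is the readout of "Notch activity"
everywhere, since releasing `S` is the only productive outcome of any
receptor–ligand interaction in the equations.

The general single-cell system is

```
dL/dt  = b_L − βL − 2 k_d L² − (k1·N_ext + k3·N + k5·N)·L
dL*/dt = k_d L² − βL* − (k2·N_ext + k4·N + k6·N)·L*
dN/dt  = b_N − βN − (k1·L_ext + k2·L*_ext + k3·L + k4·L* + k5·L + k6·L*)·N
dS/dt  = (k1·L_ext + k2·L*_ext + k5·L + k6·L*)·N − β_S·S
```

`k1/k2` are trans-activation by neighbour monomers/dimers, `k3/k4`
cis-inhibition by same-cell monomers/dimers (non-productive), `k5/k6`
cis-activation (productive).  Every named variant is a rate assignment,
not a separate code path:

* **mutual inactivation (MI)** — `k_d = 0`, `k1 = k_t`, `k3 = k_ci`:
  same-cell monomers and receptors titrate each other;
* **monomer-trans / dimer-cis (T1)** — `k1 = k_t`, `k4 = k_ci`, the rest 0:
  the favoured configuration, in which only dimers cis-inhibit;
* **cis configurations C1/C2/C3** and **trans configurations T1/T2/T3**
  assign `(k3, k4)` and `(k1, k2)` to test monomer-, dimer- or
  both-mediated cis-inhibition and trans-activation;
* **cis-activation scenarios 1/2/3** assign `(k5, k6)` for an isolated
  cell (`L_ext = L*_ext = N_ext = 0`), always with `k4 = k_ci`.

Two structural extensions: the **oligomer model** replaces dimerization by
`n`-mer formation (monomer drain `n·k_d·Lⁿ`, oligomer gain `k_d·Lⁿ`; the
homogeneous-population form — one oligomer size per simulation); the
**compartmental model** splits the cell into cytoplasm and membrane with
transport rate `k_r`: dimerization and dimer cis-inhibition are
cytoplasmic, trans-/cis-activation act on membrane pools.

No dimer dissociation is modelled (the forward reaction only), there is no
transcriptional feedback of `S` on production rates, and no ligand
hetero-dimers.  Negative states or rates are rejected with a validation
error rather than clamped, so integration bugs surface.

## Parameters

Baseline values (units as stated; "molec" = molecules per cell):

| parameter | meaning | baseline | units |
|---|---|---|---|
| b_L, b_N | ligand / receptor production | 200 | molec·h⁻¹ |
| k_d | oligomerization rate | 1e-4 | molec⁻⁽ⁿ⁻¹⁾·h⁻¹ |
| k_t | trans-activation | 5e-5 | molec⁻¹·h⁻¹ |
| k_ci | cis-inhibition | 6e-4 | molec⁻¹·h⁻¹ |
| k_ca | cis-activation | 5e-6 | molec⁻¹·h⁻¹ |
| β | protein degradation | 0.1 | h⁻¹ (half-life ≈ 7 h) |
| β_S | signal degradation | 0.5 | h⁻¹ |
| k_r | cytoplasm→membrane transport | 0.1 | h⁻¹ |

Single cells exposed to a trans bath see `L_ext = 1500` molecules.  In
coupled-cell and lattice settings the trans input of a cell is the
arithmetic mean of its neighbours' ligand levels (boundary cells average
over the neighbours they have).  Cis-activation rates are zeroed whenever
external trans ligand is present; cis-activation is only simulated for
isolated cells.

## Steady states

MI and T1 admit closed forms.  Both reduce to a quadratic whose "+"-branch
root is the unique non-negative solution (the "−" branch is provably
negative for positive parameters; a debug assertion checks the returned
root's sign).  With effective rates `β₁ = β + k_t·N_ext`,
`β₂ = β + k_t·L_ext`:

* MI: `L̄ = h + sqrt(h² + β₂·b_L/(β₁·k_ci))` with
  `h = (b_L−b_N)/(2β₁) − β₂/(2k_ci)`; `N̄ = (β₁L̄ − (b_L−b_N))/β₂`;
  `S̄ = k_t·N̄·L_ext/β_S`.  In the high-affinity limit the cell is either a
  *sender* (`L̄ ≈ (b_L−b_N)/β₁`, `N̄ ≈ 0`) or a *receiver* — ligand and
  receptor are mutually exclusive.
* T1: the monomer equation decouples, so
  `L̄ = sqrt((β₁/4k_d)² + b_L/2k_d) − β₁/4k_d` is **independent of b_N**;
  dimer influx `k_d L̄²` then acts as the effective ligand source in an
  MI-like quadratic for `L̄*`, and `N̄ = (βL̄* − (k_dL̄²−b_N))/β₂`.  When
  `b_N > k_d L̄²` the receptor survives (`N̄ ≈ (b_N − k_dL̄²)/β₂`): ligand
  and receptor coexist, which is what permits stable bidirectional
  signalling across a tissue boundary.

The receptor-equation forms above are the unique ones consistent with the
summed steady-state balance of the respective systems; they are
cross-validated against the numeric solver in the test suite.

`S̄ = 0` for contact-free MI/T1 cells (no productive term without trans
input); cis-activation steady states have no closed form here and come
from the numeric solver.

The numeric fixed-point solver integrates (LSODA, rtol 1e-10) until the
maximum relative state change over a trailing 10 h window falls below
1e-8 (both config-overridable), then polishes with damped root-finding
(MINPACK hybr on the smooth unclipped RHS; the candidate is accepted on
its measured residual, not the solver's progress flag, which can trip at
convergence).  The returned state must satisfy
`max |dX/dt| < 1e-8·max(b_L, b_N, 1)`; for coupled systems the scale is
the largest production rate of any member cell.

## Numerical simulation

Time courses use adaptive explicit Runge–Kutta (SciPy RK45, rtol 1e-8,
atol 1e-10) with dense-output sampling.  States are clipped to zero before
each RHS evaluation; an excursion beyond round-off tolerance aborts with
diagnostics.  Trans sweeps solve the sender and receiver as one coupled
system to joint steady state (the sender is a pure ligand source,
`b_N = 0` by default, since the assay geometry leaves sender receptor
expression unspecified; it is a parameter override away).  Two-cell
systems are the same machinery with identical cells; exchange symmetry is
preserved exactly and tested.

Dose–response curves report steady-state `S` per grid value; curves are
normalized against their maximum where comparisons across configurations
are shape-based.  Non-monotonicity is detected as a discrete-grid argmax
strictly inside the grid.

## Lattices

The tissue is a rectangular grid integrated as a single coupled ODE
system (no per-cell relaxation sweeps, so no update-order dependence).
Neighbourhoods: von Neumann (default), Moore, or hexagonal — the
patterning claims hold for all three and the tests exercise this.
Neighbour averaging is a precomputed row-stochastic sparse operator.

Two-ligand tissues (dorsoventral boundary) extend T1 minimally: each
species follows its own monomer/dimer equations; the receptor equation
sums cis-inhibition over species and trans-activation over
Fringe-permitted species; `dS` sums the permitted trans terms.  Fringe
gating is binary — Notch in dorsal cells is trans-activatable only by
Delta, in ventral cells only by Serrate — and symmetric: the receptor
level a ligand sees in its neighbours (`N_ext`) is likewise masked to the
cells its species may bind.  Delta production is ventral-only by default
(dorsal Delta is a configuration option).  Hetero-dimers are out of scope.

Defaults: 20×20 grid; wing-vein setting `b_N = 200`/h with ligand
production `b_L(y) = L_max·e^(−|y−y0|)`, `L_max = 15000`/h peaked at the
central row; dorsoventral setting `b_N = 1000`/h ("receptor in excess"),
`b_L = 200`/h per compartment ligand.  Ectopic stripes reuse the
exponential profile with configurable species, centre row and `k_d`.
Lattice steady states must zero every cell's RHS to `1e-6·max(b_N)`;
chunked RK45 integration is followed, when needed, by a Jacobian-free
Newton–Krylov polish (integration accuracy alone stalls around
1e-8·state-scale, which for ectopic-stripe runs with states ~1e5
molecules sits above the absolute tolerance).

Tests use 12–16-row grids (columns are homogeneous in these settings, so
width adds cost, not information); the shipped presets use the 20×20
default.

## Sensitivity analysis

One-at-a-time fold changes {0.1, 0.2, 0.5, 1, 2, 5, 10} (config-
overridable) of each parameter in three settings: fixed trans bath,
two identical cells, isolated cell with cis-activation (scenario 1).  The
summary index is |d log S̄ / d log θ| by central difference with factor
1.05 at fold 1.  The index is undefined (reported as null) when baseline
S̄ = 0.  `β_S` scores exactly 1 in every setting (S̄ ∝ 1/β_S); the
trans-activation rate scores exactly 0 in the isolated cell.  Whether the
underlying analysis varied parameters jointly is not documented for the
reference setting; one-at-a-time is assumed here.

## What the simulations do and do not show

All computation is deterministic ODE integration — no molecular noise, no
cell division, growth, movement or mechanics, no Fringe enzyme kinetics
(gating only), no delay terms.  Parameter values are order-of-magnitude
estimates, so the package's claims are qualitative (monotonicity, peak
position, stripe presence/absence), not quantitative fits; the closed
forms and their numeric cross-validation are exact statements about the
model, not about cells.  Conclusions about real tissue rest on the model
structure being right; the tests establish internal consistency and the
robustness of the qualitative patterns to oligomer size, subcellular
localization and lattice topology.

## Known limitations

* The cis-activation plateau of scenario 3 at high ligand production is
  `k6·b_N/((k_ci+k6)·β_S)` — about 30% of the curve's peak at baseline
  rates.  "Not suppressed" is therefore a comparative statement against
  scenario 1 (which falls to ~3% of peak), not "above half of peak".
* `numeric_fixed_point` assumes a unique attracting steady state from the
  empty-cell initial condition; none of the configurations here is
  bistable, but the solver does not verify uniqueness.
* The wing-vein and boundary patterns are reported at steady state only;
  transient pattern formation is available through the trajectory API but
  not characterized.
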
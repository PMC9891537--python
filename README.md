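# notchdimer

Deterministic ODE models of Notch signalling in which **ligand dimers —
not monomers — mediate cis-inhibition** of the receptor, from single cells
to tissue lattices.

Notch receptor activity in a cell is a balance of *trans-activation* by
ligand on neighbouring cells and *cis-inhibition* (plus weaker
*cis-activation*) by ligand in the same cell.  Classic "mutual
inactivation" models let same-cell ligand monomers and receptors titrate
each other, which forbids a cell from holding high levels of both.  This
package implements an alternative in which ligand monomers self-associate
(rate `k_d`) and only the dimers cis-inhibit, while monomers carry
trans-activation.  That one change lets ligand and receptor coexist in a
cell — and with it, stable bidirectional signalling at tissue boundaries.

For a cell with ligand monomer `L`, dimer `L*`, receptor `N` and free
intracellular domain `S` (the activity readout), the favoured
configuration ("T1") reads

```
dL/dt  = b_L − βL − 2 k_d L² − k_t N_ext L
dL*/dt = k_d L² − βL* − k_ci N L*
dN/dt  = b_N − βN − k_ci L* N − k_t L_ext N
dS/dt  = k_t L_ext N − β_S S
```

with `L_ext`, `N_ext` the ligand/receptor presented by neighbours.  The
package provides the full rate-assignment family around this (general
model with six interaction rates, mutual inactivation, cis-activation
scenarios, oligomer sizes n ≥ 2, a cytoplasm/membrane compartment split),
closed-form steady states with an independent numeric fixed-point solver,
dose–response sweep and coupled-cell machinery, lattice simulations of
wing-vein and dorsoventral-boundary patterning with binary Fringe gating,
and a local parameter-sensitivity scan.  See `docs/methods.md` for the
science and the numerical choices.

## Worked example

```python
import numpy as np
from notchdimer import (ModelParameters, ExternalSignal, t1_steady_state,
                        two_cell_production_sweep)

p = ModelParameters.t1()                 # baseline rates, dimer-cis kinetics
bath = ExternalSignal(L_ext=1500.0)      # fixed trans-ligand bath

L, Ls, N, S = t1_steady_state(p, bath)
print(f"L = {L:.1f}  L* = {Ls:.1f}  N = {N:.1f}  S = {S:.1f}")
```

prints

```
L = 780.8  L* = 99.8  N = 851.5  S = 127.7
```

— the cell keeps ~780 ligand monomers *and* ~850 receptors at once
(coexistence), with activity S = 127.7 driven by the bath.  The monomer
level is set by its own production and dimerization only; receptor
production does not touch it:

```python
for b_N in (0.0, 200.0, 2000.0):
    print(b_N, t1_steady_state(p.with_(b_N=b_N), bath)[0])
# 780.7764 at every b_N
```

Two identical coupled cells show the signature of dimer-mediated
cis-inhibition — activity rises with ligand production, peaks, then
collapses as each cell's own dimers titrate its receptors:

```python
res = two_cell_production_sweep("T1", np.linspace(0, 4000, 9))
print(res.activity.round(3))
# [0.    1.    0.438 0.294 0.232 0.197 0.173 0.157 0.144]
```

## Command line

Each shipped preset runs one simulation scenario end to end:

```
notchdimer sweep    --config src/notchdimer/presets/cis_production_sweep.yaml --out results/
notchdimer lattice  --config src/notchdimer/presets/dv_boundary_t1.yaml      --out results/
notchdimer simulate --config src/notchdimer/presets/ligand_pulse.yaml        --out results/ --plot
```

Outputs are comma-delimited tables with a `#` metadata header (model tag,
parameter snapshot, package version); `--plot` additionally writes a PNG.
Subcommands: `simulate`, `sweep`, `two-cell`, `lattice`, `sensitivity`.

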
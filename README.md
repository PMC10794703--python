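# fibrilstab

Structural analysis toolkit for amyloid fibril polymorphism, built around
the cardiac transthyretin (ATTR) fibril system: solvation-based fibril
stabilization energy, helical symmetry geometry, per-residue polymorph
comparison, and filament-level polymorph co-occurrence tracing — all
exercisable on synthetic fibril models and particle tables, with the same
code paths accepting deposited PDB/mmCIF coordinates and refinement STAR
files.

## Who this is for

Structural biologists working with cryo-EM fibril models who want, from a
set of atomic coordinates and particle metadata:

1. **Helical geometry** — the screw operator (twist θ in degrees/subunit,
   rise *h* in Å/subunit) relating consecutive cross-β layers, the derived
   crossover distance *c* = (180/|θ|)·*h*, symmetry expansion of a single
   layer into a stack, and re-estimation of (θ, *h*) from stacked
   coordinates by consecutive-layer least-squares superposition.
2. **Stabilization energy** — per-atom solvent-accessible surface area
   (Shrake–Rupley), the area ΔA<sub>i</sub> each atom buries upon
   incorporation into the fibril stack, and the solvation energy
   e<sub>i</sub> = σ<sub>i</sub>·(A<sub>i</sub><sup>stack</sup> −
   A<sub>i</sub><sup>ref</sup>) from per-class atomic solvation parameters
   σ (cal·mol⁻¹·Å⁻²), summed per residue and per chain
   (stabilizing = negative kcal/mol), plus a Mann–Whitney comparison of a
   fibril cohort against a broader amyloid-structure cohort.
3. **Polymorph comparison** — Kabsch superposition over a configurable fit
   set (all shared residues, or the common core Leu12–Lys35 ∪ Gly67–Val122
   conserved across the ATTR gate polymorphs), overall r.m.s.d. and
   per-residue Cα deviation profiles, and pairwise deviation matrices.
4. **Filament tracing** — reading refinement particle tables (STAR),
   grouping segments into filaments by helical tube id or proximity
   chaining, and quantifying whether distinct polymorph classes co-occur
   within single fibrils (a lower bound under incomplete coverage).

A first-class synthetic-data module generates idealized cross-β layers
(two transthyretin-like fragments per layer, four channel-gate
conformations: closed, open, absent, broken) and particle tables with
known ground truth, so every stage is testable without downloads.

## Worked example

```python
from fibrilstab import (crossover_distance, make_fibril, attr_like_layer_spec,
                        HelicalParameters, GateState, stabilization_energy,
                        fold_rmsd)

# crossover from the helical parameters of the absent-gate polymorph
print(round(crossover_distance(-1.3, 4.93)))        # 683  (Å)

# a 5-layer synthetic closed-gate fibril, scored for stability
fib = make_fibril(attr_like_layer_spec(GateState.CLOSED),
                  HelicalParameters(-1.26, 4.81), 5)
prof = stabilization_energy(fib, stack_layers=5, n_points=480)
print(round(prof.chain_energy, 1))                  # -59.6  (kcal/mol)

# closed vs open gate: core superposes, the gate swings out
open_fib = make_fibril(attr_like_layer_spec(GateState.OPEN),
                       HelicalParameters(-1.26, 4.81), 3)
p = fold_rmsd(fib, open_fib, layers=3, fit_set="COMMON_CORE")
print(round(p.rmsd, 3), round(p.per_residue.max(), 1))   # 0.009 19.0  (Å)
```

The crossover (683 Å) is the axial distance over which the fibril's
projection rotates 180°; the chain energy (−59.6 kcal/mol) is the
solvation free-energy gain of one layer on stacking (negative =
stabilizing); the r.m.s.d. pair (0.009 Å over the fitted common core
vs a 19 Å maximum per-residue deviation) shows the two polymorphs differ
only in the channel gate.

Longer narrative scripts, one per capability, live in `examples/`; a thin
CLI (`fibrilstab helix|stability|compare|trace|synth|run`) mirrors the
library for shell use.

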
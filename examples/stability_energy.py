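"""Solvation stabilization energy of a fibril chain, and the cohort test.

Scores the central chain of a 5-layer synthetic fibril stack: for every
atom, the solvent-accessible area it buries on stacking is multiplied by
an atomic solvation parameter for its chemical class; sums per residue
and per chain give the stabilization energy (negative = stabilizing).
Then the shipped stability snapshot (7 fibril chains vs 86 other amyloid
structures) is compared with a two-sided Mann-Whitney U test.
"""

from fibrilstab import (
    GateState,
    HelicalParameters,
    atlas_comparison,
    attr_like_layer_spec,
    make_fibril,
    residue_energy_colormap,
    stabilization_energy,
)

fibril = make_fibril(
    attr_like_layer_spec(GateState.CLOSED), HelicalParameters(-1.26, 4.81), 5
)
profile = stabilization_energy(fibril, stack_layers=5, n_points=480)

print(f"chain energy: {profile.chain_energy:.1f} kcal/mol "
      "(negative = stacking is stabilizing)")
best = profile.per_residue.nsmallest(3)
print("three most stabilizing residues (kcal/mol):")
for res, e in best.items():
    print(f"  residue {res}: {e:+.2f}")
print("context:", {k: profile.context[k] for k in
                   ("stack_layers", "reference", "probe_A")})

colors = residue_energy_colormap(profile)
print(f"colour bins used for structure painting: "
      f"{sorted(colors['bin'].unique())} (low bin = strongly stabilizing)")

cmp = atlas_comparison()
print(f"\nfibril cohort vs {cmp.n_b} other amyloids: U = {cmp.u_statistic:.0f}, "
      f"two-sided p = {cmp.p_value:.2e} -> fibril chains are significantly "
      "more stable (medians "
      f"{cmp.box_a.median:.1f} vs {cmp.box_b.median:.1f} kcal/mol)")
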
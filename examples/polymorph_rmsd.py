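"""Polymorph comparison: overall r.m.s.d. and per-residue deviations.

Builds the four gate conformations of the synthetic ATTR-like fold,
superposes each pair over the common core with one least-squares fit, and
reports the pairwise r.m.s.d. matrix plus where the deviations live: the
channel gate moves by many Angstrom while the shared core stays fixed.
"""

from fibrilstab import (
    GateState,
    HelicalParameters,
    attr_like_layer_spec,
    deviation_matrix,
    fold_rmsd,
    make_fibril,
)

params = HelicalParameters(-1.26, 4.81)
models = {
    gs.value.lower(): make_fibril(attr_like_layer_spec(gs), params, 3)
    for gs in GateState
}

table, profiles = deviation_matrix(models, layers=3, fit_set="COMMON_CORE")
print("pairwise r.m.s.d. matrix (A), common-core fit over 3 layers:")
print(table.round(2).to_string())

prof = fold_rmsd(models["closed"], models["open"], layers=3, fit_set="COMMON_CORE")
gate = prof.per_residue.loc[58:62]
core = prof.per_residue.drop(range(58, 63), errors="ignore")
print(f"\nclosed vs open: overall {prof.rmsd:.3f} A over the fitted core;")
print(f"gate residues deviate up to {gate.max():.1f} A "
      f"(core max {core.max():.2f} A) -> the difference is localized to the gate")
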
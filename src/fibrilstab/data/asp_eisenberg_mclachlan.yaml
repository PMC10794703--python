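# Atomic solvation parameters, cal/(mol * Angstrom^2).
# Five-class set of Eisenberg & McLachlan (1986): free energy per unit area
# of transferring the atom class from the protein interior to water.
# Positive sigma (apolar C, S): burial is favourable (stabilizing, negative
# energy under this package's sign convention); negative sigma (polar and
# charged N/O): burial costs free energy.
provenance: "Eisenberg & McLachlan (1986) five-class atomic solvation parameters"
units: cal/(mol*A^2)
classes:
  C_APOLAR: 16.0
  N_O_NEUTRAL: -6.0
  O_CHARGED: -24.0
  N_CHARGED: -50.0
  S: 21.0
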
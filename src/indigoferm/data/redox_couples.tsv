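# Template couples file for the mediator feasibility calculation.
# e_ref_mV is the midpoint potential (mV vs SHE) at pH_ref; m and n are
# the protons and electrons transferred by the half-reaction. Reference
# midpoint potentials are NOT shipped: fill them in from your preferred
# compilation before use (rows with empty fields are skipped).
name	e_ref_mV	pH_ref	m	n
NADH
FMN
riboflavin
acetaldehyde
anthraquinone
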
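# SYNTHETIC uremic-toxin inhibitor panel for severe renal impairment.
# Concentrations are literature-plausible high-end plasma levels (µM); the
# per-toxin inhibition constants (Ki, µM) are back-constructed so that the
# aggregate competitive-inhibition factors R = Σ [I]/Ki equal 26.6 for
# CYP3A4, 2.4 for CYP2C9 and 2.5 for UGT2B7. The individual splits are not
# measured values and must not be cited as such.
name: uremic_default
toxins:
  - name: benzyl_alcohol
    concentration: 330.0
    ki:
      CYP3A4: 50.0        # contributes R 6.6
  - name: indoxyl_sulfate
    concentration: 940.0
    ki:
      CYP3A4: 94.0        # contributes R 10.0
      UGT2B7: 1175.0      # contributes R 0.8
  - name: p_cresol
    concentration: 600.0
    ki:
      CYP3A4: 60.0        # contributes R 10.0
      CYP2C9: 500.0       # contributes R 1.2
      UGT2B7: 1200.0      # contributes R 0.5
  - name: hippuric_acid
    concentration: 2400.0
    ki:
      CYP2C9: 2000.0      # contributes R 1.2
      UGT2B7: 2000.0      # contributes R 1.2
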
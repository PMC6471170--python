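# Zidovudine — HIV antiviral, weakly bound, eliminated mainly by UGT2B7
# glucuronidation with a modest renally filtered fraction of parent drug.
# Approximate parameterization from public literature values.
name: zidovudine
mw: 267.2
fu: 0.80
bp_ratio: 1.0
ka: 2.2
f_abs: 0.95
f_gut: 1.0
vss_per_kg: 1.6      # L/kg at fu 0.80
renal_filtration_fraction: 0.18
pathways:
  - enzyme: UGT2B7
    vmax: 1.1        # pmol/min/pmol enzyme
    km: 940.0        # µM — high-KM glucuronidation, linear at clinical doses
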
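# Sildenafil — PDE5 inhibitor, highly bound, cleared by CYP3A4 (major)
# and CYP2C9 (minor) with negligible renal excretion of parent drug.
# Approximate parameterization from public literature values.
name: sildenafil
mw: 474.6
fu: 0.036
bp_ratio: 0.62
ka: 1.4
f_abs: 0.92
f_gut: 0.84
vss_per_kg: 1.2      # L/kg at fu 0.036
renal_filtration_fraction: 0.0
pathways:
  - enzyme: CYP3A4
    vmax: 12.0
    km: 6.0
  - enzyme: CYP2C9
    vmax: 4.0
    km: 21.0
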
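# Nifedipine — calcium channel blocker, highly bound, eliminated almost
# entirely by CYP3A4/CYP3A5 oxidation with negligible renal clearance.
# Approximate parameterization assembled from public literature values;
# intended for mechanistic/directional simulation, not bioequivalence work.
name: nifedipine
mw: 346.3            # g/mol
fu: 0.039            # fraction unbound in plasma
bp_ratio: 0.59       # blood:plasma ratio (restricted to plasma water/protein)
ka: 2.0              # 1/h, immediate-release oral
f_abs: 1.0           # essentially complete absorption
f_gut: 0.78          # escapes intestinal CYP3A extraction
vss_per_kg: 0.8      # L/kg at fu 0.039
renal_filtration_fraction: 0.0
pathways:
  - enzyme: CYP3A4
    vmax: 17.0       # pmol/min/pmol enzyme
    km: 9.6          # µM unbound
  - enzyme: CYP3A5
    vmax: 8.0
    km: 12.0
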
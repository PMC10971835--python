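# Baseline dialyzer representative unit, urea (validation solute).
# Lengths in mm, flows in mL/min, pore diameter in nm, concentration in mol/L.

[geometry]
r1_mm = 0.1
r2_mm = 0.145
r3_mm = 0.210
L_mm = 270.0
N = 12000

[operating]
tube_flow_mL_min = 300.0
shell_flow_mL_min = 500.0

[solute]
name = "urea"
MW_Da = 60.0
rs_nm = 0.24
C_in_mol_L = 1.0
# Ds omitted: auto-filled from the molecular-weight correlation.

[membrane]
pore_diameter_nm = 39.5
porosity = 0.1
tortuosity = 2.27
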
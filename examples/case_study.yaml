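# Thin-film PCL-lipase case study: 0.5 mm film (half-thickness 0.25 mm),
# 30.2% initial crystallinity, calibrated rate constants.
kinetics:          # first-order rate constants, 1/h
  k1: 0.65         # enzyme binding to crystalline polymer
  k_m1: 0.47       # dissociation from crystalline complex
  k3: 0.3          # enzyme binding to amorphous polymer
  k_m3: 0.03       # dissociation from amorphous complex
  k_conv: 0.58     # amorphisation of bound crystalline material
  k_deg_C: 0.0012  # crystalline enzymolysis
  k_deg_A: 0.005   # amorphous enzymolysis
transport:
  De0: 1.66        # baseline enzyme diffusivity in dense polymer, mm^2/h
  alpha_e: 1.0     # dimensionless porosity-diffusivity coupling
geometry:
  L_mm: 0.25       # half-thickness, mm (full film = 2L)
  N: 25            # grid nodes (omit to use the dx <= 0.0104 mm rule)
initial:
  C0: 0.302        # initial crystalline volume fraction
  A0: 0.698        # initial amorphous volume fraction (C0 + A0 = 1)
solver:
  t_end_h: 72.0
  output_times_h: [0.0, 4.0, 8.0, 16.0, 20.0, 24.0, 40.0, 64.0]
  rtol: 1.0e-06
  atol: 1.0e-09
  max_step_h: 0.5
  method: BDF      # or LSODA (banded fast path)
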
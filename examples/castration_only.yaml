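# Castration-only reference arm at the shipped desk-scale calibration.
# Only overridden keys need to appear; everything else takes the package
# defaults (materialised on load).  Units: probabilities per 2-h step,
# rates per hour, diffusion in site^2/h, times in hours.
lattice_n: 50
spacing_um: 150.0
replicates: 20
seed: 0
timeline:
  castration_h: 672.0   # week 4
  horizon_h: 1512.0     # 9 weeks
regimen:
  castration: true
  anti_wnt5a: 0.0
  csf1r_inhibitor: 0.0
  anti_il2: 0.0
  egfr_inhibitor: 0.0
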
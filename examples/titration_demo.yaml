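# Desk-scale demo titration: four ligand concentrations, ground-truth
# K_D = k_off/k_on = 50 uM. Runs in about two minutes.
conditions:
  - {label: gq_1uM,  ligand_conc_uM: 1.0,  k_on: 0.07, k_off: 3.5}
  - {label: gq_5uM,  ligand_conc_uM: 5.0,  k_on: 0.07, k_off: 3.5}
  - {label: gq_20uM, ligand_conc_uM: 20.0, k_on: 0.07, k_off: 3.5}
  - {label: gq_40uM, ligand_conc_uM: 40.0, k_on: 0.07, k_off: 3.5}
simulation:
  duration: 6.0
  dt: 8.0
  diffusion_stride: 8
  diffusion_G: 2.5
  diffusion_R: 2.5
  diffusion_GR: 2.5
analysis:
  max_lag_s: 0.01
  n_chunks: 6
  kinetics: false
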
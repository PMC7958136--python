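# End-to-end demo: simulate every input at the published study conditions,
# then run conductance -> inhibition -> fcs_count -> turnover.
seed: 7
temperature_K: 306.0
membrane_area_cm2: 1.13e-4      # ~120 um bilayer aperture
buffer:
  Na2SO4_mM: 50.0
  Tris_mM: 10.0
  MES_mM: 10.0
  EGTA_mM: 0.6
  pH_cis: 7.34
  pH_trans: 7.34
  pH_shifted_cis: 8.34          # Tris addition on the cis side, delta pH = 1.0
lipid_composition: {PC: 45.0, PE: 45.0, CL: 10.0}
fatty_acid: {species: AA, mol_percent: 15.0}
stages: [simulate, conductance, inhibition, fcs_count, turnover]
simulate:
  iv:
    G_total: 1750.0             # carrier + arachidonic acid, nS/cm^2
    G_control: 440.0            # arachidonic acid alone
    reversal_shift_mV: 49.0     # zero-current shift imposed on the pH-gradient trace
    noise_sd_current: 0.5       # pA
  dose:
    noise_cv: 0.05
    compounds:
      CATR: {ec50_uM: 18.9, imax_pct: 64.2}
      BA: {ec50_uM: 32.3, imax_pct: 44.3}
  fcs:
    n_before: 1.60              # proteoliposomes per confocal volume
    tauD_before_s: 1.45e-3
    n_after: 13.83              # micelles after 2% SDS
    tauD_after_s: 1.0e-4
    noise_scale: 0.02
analysis:
  fit_window_mV: [-50, 50]
  n_boot: 300
  radius_nm: 50.0
  area_per_lipid_nm2: 0.6
  g_mode: protein               # carrier-mediated conductance: total minus FA-only control
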
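kinetic_params:
  k_tx: 1.0
  k_z: 0.055
  delta_z: 0.008
  K_z: 1.0
  hill_h: 8.0
  delta_m0: 0.015
  alpha_fos: 3.08
  K_deg: 0.6
  k_tl: 0.05
  eps_min: 0.05
  k_damage: 0.025
  delta_p_yfp: 0.0012
  delta_p_dgfp: 0.012
  delta_p_degron: 0.012
  f_stab: 0.95
  m_over: 1.0
  m_sponge: 0.0
  k_leak: 0.01
  background_yfp_au: 861.0
  background_gfp_au: 51.5
  btg2_promoter_scale: 1.0
  erk_smoothing_min: 0.0
circuit_presets:
  fos-tubulin:
    promoter: FOS
    utr5: FOS
    utr3: TUBULIN
    degron: NONE
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  fos-btg2:
    promoter: FOS
    utr5: FOS
    utr3: BTG2
    degron: NONE
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  fos-fos:
    promoter: FOS
    utr5: FOS
    utr3: FOS
    degron: NONE
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  btg2-fos:
    promoter: BTG2
    utr5: BTG2
    utr3: FOS
    degron: NONE
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  btg2-btg2:
    promoter: BTG2
    utr5: BTG2
    utr3: BTG2
    degron: NONE
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  fos-fra1deg-fos:
    promoter: FOS
    utr5: FOS
    utr3: FOS
    degron: FRA1
    reporter: msfYFP
    n_sites: 8
    mir21_status: ENDOGENOUS
  and-gate:
    promoter: FOS
    utr5: FOS
    utr3: BTG2
    degron: NONE
    reporter: dGFP
    n_sites: 8
    mir21_status: ENDOGENOUS
stimulus_presets:
  starve:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.0
    light_windows: []
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 0.0
  serum10:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.1
    light_windows: []
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 24.0
  serum1:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.01
    light_windows: []
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 24.0
  transient20:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.0
    light_windows:
    - - 0.0
      - 20.0
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 0.0
  sustained:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.0
    light_windows:
    - - 0.0
      - 180.0
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 0.0
  sustained90:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.0
    light_windows:
    - - 0.0
      - 90.0
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 0.0
  dox:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.0
    light_windows: []
    doxorubicin_nM: 860.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 0.0
  serum1+dox:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.01
    light_windows: []
    doxorubicin_nM: 860.0
    cycloheximide: false
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 24.0
  serum10+chx:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.1
    light_windows: []
    doxorubicin_nM: 0.0
    cycloheximide: true
    meki_time_min: null
    drug_addition_time_min: 0.0
    erk_tau_min: 24.0
  serum10+meki30:
    duration_min: 180.0
    dt_min: 2.0
    serum_fraction: 0.1
    light_windows: []
    doxorubicin_nM: 0.0
    cycloheximide: false
    meki_time_min: 30.0
    drug_addition_time_min: 0.0
    erk_tau_min: 24.0
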
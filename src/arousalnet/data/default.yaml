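neuron:
  tau_m_E: 0.02
  tau_m_I: 0.02
  V_thresh_E: 1.5
  V_thresh_I: 0.75
  V_r_E: 0.0
  V_r_I: 0.0
  tau_ref_E: 0.005
  tau_ref_I: 0.005
  tau_syn_E: 0.002
  tau_syn_I: 0.002
architecture:
  N_E: 1600
  N_I: 400
  p: 18
  f_E: 0.05
  f_I: 0.05
  p_EE: 0.2
  p_EI: 0.5
  p_IE: 0.5
  p_II: 0.5
  j_EE: 0.42
  j_EI: 0.5
  j_IE: 0.42
  j_II: 0.9
  jplus_factor_EE: 15.75
  jplus_factor_EI: 5.0
  jplus_factor_IE: 5.0
  jplus_factor_II: 5.0
  C_ext_E: 80
  C_ext_I: 320
  j_ext_E: 5.6
  j_ext_I: 1.22
  nu_o_E: 7.0
  nu_o_I: 7.0
arousal:
  kind: heterogeneity
  dH_E: 0.0
  dH_I: 0.0
stimulus:
  n_stimuli: 5
  frac_clusters: 0.5
  frac_cells: 0.5
  A_stim_E: 0.07
  tau_r: 0.05
  tau_d: 0.15
  t_stim: 1.0
simulation:
  dt: 5.0e-05
  trial_duration: 3.5
  t_stim: 1.0
  n_trials_per_stimulus: 30
  seed: 0
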
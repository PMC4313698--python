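# Example run configuration: every key is optional and overrides the
# package default. Sections: network (geometry, dynamics, synapses),
# hebb (plasticity rates), protocol (training stimuli and SOA).
network:
  tactile:
    spacing: 0.5
    rf_width: 0.5
    tau: 20.0
    lateral: {L_ex: 0.15, sigma_ex: 1.0, L_in: 0.02, sigma_in: 3.0}
  auditory:
    spacing: 2.0
    rf_width: 6.0
    lateral: {L_ex: 0.20, sigma_ex: 3.0, L_in: 0.015, sigma_in: 12.0}
  ms_unit:
    tau: 20.0
    slope: 0.12
    theta: 35.0
  synapses:
    w_max: 1.0
    profile_d0: 54.0      # cm, basal auditory half-decay distance
    profile_width: 4.0    # cm
    feedback_gain_t: 2.0
    feedback_gain_a: 2.0
  dt: 0.5                 # ms
  steady_tol: 1.0e-5      # max |dy| per ms at steady state

hebb:
  gamma_pot: 2.4e-4       # 1/ms
  gamma_forget: 1.0e-6    # 1/ms
  w_max: 1.0

protocol:
  n_presentations: 30
  soa_range: [250.0, 750.0]   # ms, |SOA| bounds (asynchronous mode)
  tactile_stim:
    modality: tactile
    center: [10.0, 5.0]
    spatial_sigma: 2.0
    intensity: 10.0
    duration: 300.0
  auditory_stim:
    modality: auditory
    center: [100.0, 5.0]
    spatial_sigma: 2.0
    intensity: 10.0
    duration: 300.0
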
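# Example arcsim run configuration.
# Every key is optional; omitted keys take the documented defaults.
# Unknown keys are rejected, so typos fail fast.

subject:                      # overrides for the synthetic subject
  anesthetic: ketamine        # ketamine | isoflurane | propofol
  weight: 40.0                # kg
  wb_slope: 0.03              # mmHg per mL (pressure-volume responsiveness)
  noise_sd: 2.0               # mmHg additive noise on pressure channels

arc:                          # adaptive resuscitation controller
  target_map: 65.0            # mmHg, permissive-hypotension target
  pace: 6.0                   # mmHg/min resuscitation pace
  q_max: 250.0                # mL/min pump bound
  cvp_threshold: 15.0         # mmHg over-resuscitation safety threshold

autobleed:                    # hemorrhage controller
  target_map: 35.0            # mmHg hypotensive target
  cpda_ratio: 7.0             # blood:anticoagulant volumetric ratio

protocol:                     # study timeline
  hold_lactate_threshold_1: 4.0   # mmol/L, first-hold shock criterion
  hold_max_duration: 90.0         # min
  hold_lactate_cap_2: 6.0         # mmol/L, second-hold cap
  lactate_sampling_interval: 10.0 # min

seed: 42                      # master seed; runs are bit-reproducible
jitter: 0.0                   # cohort variability (coefficient of variation)
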
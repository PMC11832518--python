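# Default axial linkage of an infant rat (lengths in metres).
linkage:
  zero_direction: [1, 0, 0]
  up: [0, 0, 1]
  snout_keypoint: snout
  segments:
    - {name: pelvis, proximal: tail_base, distal: mid_spine, rest_length: 0.04}
    - {name: torso,  proximal: mid_spine, distal: neck_base, rest_length: 0.05}
    - {name: head,   proximal: neck_base, distal: snout,     rest_length: 0.03}
  appendages:
    order_posterior_to_anterior: [hind_feet, fore_feet]
    sets:
      hind_feet: [left_hind_foot, right_hind_foot]
      fore_feet: [left_fore_foot, right_fore_foot]
params:
  quantum: 45.0
  likelihood_threshold: 0.6
  min_amplitude_deg: 11.25
  speed_threshold_deg_s: 10.0
  plane_tolerance_deg: 22.5
  contact_threshold: 0.02
  immobility_speed_threshold: 0.002
  immobility_min_duration_s: 2.0
  warmup_reset_s: 5.0
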
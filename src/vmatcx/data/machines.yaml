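# Machine templates for vmatcx.
#
# Geometry is in cm at the isocenter plane.  The delivery limits under
# `constraints` (max gantry speed, dose rate, leaf speed, dose-rate bins) are
# ASSUMPTIONS chosen as typical for each machine class — edit them to match
# your own linac commissioning data.  Leaf boundaries are rebuilt from the
# width list, symmetric about the beam central axis.
machines:
- name: millennium120
  n_pairs: 60
  leaf_widths: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
                0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
                0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
                0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
                1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  overtravel: 15.0
  min_gap: 0.0
  constraints:
    max_gantry_speed: 4.8     # deg/s, assumed
    max_dose_rate: 600.0      # MU/min, assumed
    dose_rate_mode: continuous
    dose_rate_bins: null
    max_leaf_speed: 2.5       # cm/s, assumed
- name: elekta_mlci
  n_pairs: 40
  leaf_widths: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  overtravel: 12.5
  min_gap: 0.0
  constraints:
    max_gantry_speed: 6.0     # deg/s, assumed
    max_dose_rate: 600.0      # MU/min, assumed
    dose_rate_mode: binned
    dose_rate_bins: [600.0, 300.0, 150.0, 75.0, 37.5, 18.75]
    max_leaf_speed: 2.0       # cm/s, assumed
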
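# Body-segment inertial parameters for the 12-segment model.
#
# Values follow the de Leva (1996) adjustment of Zatsiorsky's male data.
# The head is folded into the torso entry and the hands into the forearm
# entries so that the 12 modeled segments account for the full body mass
# (fractions sum to 1.0).
#
# Per segment:
#   mass_fraction : segment mass / total body mass
#   com_fraction  : COM location along the longitudinal axis, as a fraction
#                   of segment length measured from the proximal end
#   radii         : principal radii of gyration [sagittal, transverse,
#                   longitudinal] as fractions of segment length, about the
#                   segment COM
segments:
  pelvis:
    mass_fraction: 0.1117
    com_fraction: 0.50
    radii: [0.615, 0.551, 0.587]
  torso:
    mass_fraction: 0.3923
    com_fraction: 0.45
    radii: [0.372, 0.347, 0.191]
  thigh_l: &thigh
    mass_fraction: 0.1416
    com_fraction: 0.4095
    radii: [0.329, 0.329, 0.149]
  thigh_r: *thigh
  shank_l: &shank
    mass_fraction: 0.0433
    com_fraction: 0.4459
    radii: [0.255, 0.249, 0.103]
  shank_r: *shank
  foot_l: &foot
    mass_fraction: 0.0137
    com_fraction: 0.4415
    radii: [0.257, 0.245, 0.124]
  foot_r: *foot
  upper_arm_l: &upper_arm
    mass_fraction: 0.0271
    com_fraction: 0.5772
    radii: [0.285, 0.269, 0.158]
  upper_arm_r: *upper_arm
  forearm_l: &forearm
    mass_fraction: 0.0223
    com_fraction: 0.4574
    radii: [0.276, 0.265, 0.121]
  forearm_r: *forearm
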
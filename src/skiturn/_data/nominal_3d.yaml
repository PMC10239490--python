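# Full skier model: free pelvis, ball lumbar and hips, revolute knees/ankles
# (19 unlocked coordinates), subtalar and mtp joints locked, arms welded to the
# trunk in a typical skiing position. Segment masses/inertias follow standard
# anthropometric scaling to the subject (height 1.90 m, mass 72 kg); they are
# editable here, not baked into code.
name: nominal_3d
subject:
  height_m: 1.90
  mass_kg: 72.0

segments:
  - {name: pelvis,  mass: 8.04,  com_offset: [-0.05, 0.0, 0.02],  inertia_diag: [0.074, 0.081, 0.084]}
  - {name: torso,   mass: 23.24, com_offset: [-0.02, 0.0, 0.25],  inertia_diag: [1.10, 0.95, 0.35]}
  - {name: head,    mass: 5.00,  com_offset: [0.0, 0.0, 0.12],    inertia_diag: [0.030, 0.032, 0.020]}
  - {name: arm_r,   mass: 3.56,  com_offset: [0.0, -0.02, -0.25], inertia_diag: [0.120, 0.120, 0.010]}
  - {name: arm_l,   mass: 3.56,  com_offset: [0.0, 0.02, -0.25],  inertia_diag: [0.120, 0.120, 0.010]}
  - {name: femur_r, mass: 10.19, com_offset: [0.0, 0.0, -0.20],   inertia_diag: [0.180, 0.180, 0.035]}
  - {name: femur_l, mass: 10.19, com_offset: [0.0, 0.0, -0.20],   inertia_diag: [0.180, 0.180, 0.035]}
  - {name: tibia_r, mass: 3.12,  com_offset: [0.0, 0.0, -0.19],   inertia_diag: [0.050, 0.050, 0.005]}
  - {name: tibia_l, mass: 3.12,  com_offset: [0.0, 0.0, -0.19],   inertia_diag: [0.050, 0.050, 0.005]}
  - {name: talus_r, mass: 0.10,  com_offset: [0.0, 0.0, -0.01],   inertia_diag: [0.001, 0.001, 0.001]}
  - {name: talus_l, mass: 0.10,  com_offset: [0.0, 0.0, -0.01],   inertia_diag: [0.001, 0.001, 0.001]}
  - {name: calcn_r, mass: 0.70,  com_offset: [0.08, 0.0, -0.02],  inertia_diag: [0.002, 0.006, 0.006]}
  - {name: calcn_l, mass: 0.70,  com_offset: [0.08, 0.0, -0.02],  inertia_diag: [0.002, 0.006, 0.006]}
  - {name: toes_r,  mass: 0.19,  com_offset: [0.03, 0.0, 0.0],    inertia_diag: [0.0002, 0.0005, 0.0005]}
  - {name: toes_l,  mass: 0.19,  com_offset: [0.03, 0.0, 0.0],    inertia_diag: [0.0002, 0.0005, 0.0005]}

joints:
  - {name: pelvis, kind: free6, parent: ground, child: pelvis, location_in_parent: [0.0, 0.0, 0.0],
     coord_names: [x, y, z, tilt, list, rot]}
  - {name: lumbar, kind: ball3, parent: pelvis, child: torso, location_in_parent: [-0.03, 0.0, 0.08],
     coord_names: [extension, bending, rotation]}
  - {name: neck, kind: locked, parent: torso, child: head, location_in_parent: [0.0, 0.0, 0.52]}
  # arms welded in a typical position: slightly abducted and forward
  - {name: shoulder_r, kind: locked, parent: torso, child: arm_r,
     location_in_parent: [0.0, -0.20, 0.45], fixed_rotation_deg: [0.0, -15.0, 20.0]}
  - {name: shoulder_l, kind: locked, parent: torso, child: arm_l,
     location_in_parent: [0.0, 0.20, 0.45], fixed_rotation_deg: [0.0, 15.0, 20.0]}
  - {name: hip_r, kind: ball3, parent: pelvis, child: femur_r, location_in_parent: [-0.05, -0.09, -0.07],
     coord_names: [flexion, adduction, rotation]}
  - {name: hip_l, kind: ball3, parent: pelvis, child: femur_l, location_in_parent: [-0.05, 0.09, -0.07],
     coord_names: [flexion, adduction, rotation]}
  - {name: knee_r, kind: revolute1, parent: femur_r, child: tibia_r, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.48], coord_names: [angle]}
  - {name: knee_l, kind: revolute1, parent: femur_l, child: tibia_l, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.48], coord_names: [angle]}
  - {name: ankle_r, kind: revolute1, parent: tibia_r, child: talus_r, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.43], coord_names: [angle]}
  - {name: ankle_l, kind: revolute1, parent: tibia_l, child: talus_l, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.43], coord_names: [angle]}
  - {name: subtalar_r, kind: locked, parent: talus_r, child: calcn_r, location_in_parent: [-0.05, 0.0, -0.04]}
  - {name: subtalar_l, kind: locked, parent: talus_l, child: calcn_l, location_in_parent: [-0.05, 0.0, -0.04]}
  - {name: mtp_r, kind: locked, parent: calcn_r, child: toes_r, location_in_parent: [0.18, 0.0, -0.01]}
  - {name: mtp_l, kind: locked, parent: calcn_l, child: toes_l, location_in_parent: [0.18, 0.0, -0.01]}

muscle_table: muscles_nominal

boot:
  neutral_angle_deg: -5.0     # slight forward lean built into the boot
  deadband_deg: 2.0
  stiffness_linear: 60.0      # N*m/rad on the effective (deadband-filtered) deflection
  stiffness_cubic: 900.0      # N*m/rad^3
  damping: 1.5                # N*m*s/rad

ski:
  n_segments: 18
  length_m: 1.70
  mass_kg: 3.40
  width_m: 0.07
  camber_height_m: 0.006
  side_cut_radius_m: 18.0
  bend_stiffness: 260.0       # N*m/rad per inter-segment joint (order-of-magnitude estimate)
  bend_damping: 1.2           # N*m*s/rad (order-of-magnitude estimate)

snow:
  # Hypoplastic penetration law: virgin-loading stiffness, unload/reload branch
  # stiffness ratio (>= 1) and a rate (dissipation) coefficient. Order-of-magnitude
  # defaults; the original laboratory-calibrated values are not published.
  k_load: 90000.0             # N/m of penetration depth per loaded contact point
  stiffness_ratio: 4.0        # unloading/reloading slope = ratio * k_load
  rate_damping: 3000.0        # N*s/m
  shear_coefficient: 60000.0  # N per m of penetration depth (lateral resistance)
  slope_angle_deg: 12.3

friction:
  mu: 0.08
  slip_epsilon: 0.001         # m/s, smooth regularization of the Coulomb law

aero:
  cda: 0.3                    # m^2 drag area
  rho: 1.07                   # kg/m^3
  wind: [0.0, 0.0, 0.0]
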
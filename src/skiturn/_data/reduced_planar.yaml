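# Reduced sagittal-plane skier for dynamic simulation and tracking at desk
# scale: planar pelvis (x, z, pitch) + hip/knee/ankle revolutes per leg = 9 DOF.
# Trunk+head+arms are welded to the pelvis; each ski is welded to its foot with
# two contact points (tail/tip regions). The planar engine projects segment
# properties onto the x-z plane (inertia about the transverse axis).
name: reduced_planar
subject:
  height_m: 1.90
  mass_kg: 72.0

segments:
  - {name: pelvis,  mass: 8.04,  com_offset: [-0.03, 0.0, 0.02], inertia_diag: [0.074, 0.081, 0.084]}
  - {name: torso,   mass: 35.36, com_offset: [0.0, 0.0, 0.28],   inertia_diag: [1.60, 1.45, 0.50]}
  - {name: femur_r, mass: 10.19, com_offset: [0.0, 0.0, -0.20],  inertia_diag: [0.180, 0.180, 0.035]}
  - {name: femur_l, mass: 10.19, com_offset: [0.0, 0.0, -0.20],  inertia_diag: [0.180, 0.180, 0.035]}
  - {name: tibia_r, mass: 3.12,  com_offset: [0.0, 0.0, -0.19],  inertia_diag: [0.050, 0.050, 0.005]}
  - {name: tibia_l, mass: 3.12,  com_offset: [0.0, 0.0, -0.19],  inertia_diag: [0.050, 0.050, 0.005]}
  - {name: foot_r,  mass: 0.99,  com_offset: [0.06, 0.0, -0.04], inertia_diag: [0.003, 0.008, 0.008]}
  - {name: foot_l,  mass: 0.99,  com_offset: [0.06, 0.0, -0.04], inertia_diag: [0.003, 0.008, 0.008]}
  - {name: ski_r,   mass: 3.40,  com_offset: [0.05, 0.0, -0.09], inertia_diag: [0.003, 0.85, 0.85]}
  - {name: ski_l,   mass: 3.40,  com_offset: [0.05, 0.0, -0.09], inertia_diag: [0.003, 0.85, 0.85]}

joints:
  - {name: pelvis, kind: planar3, parent: ground, child: pelvis, location_in_parent: [0.0, 0.0, 0.0],
     coord_names: [x, z, pitch]}
  - {name: lumbar, kind: locked, parent: pelvis, child: torso, location_in_parent: [-0.03, 0.0, 0.08]}
  - {name: hip_r, kind: revolute1, parent: pelvis, child: femur_r, axis: [0.0, 1.0, 0.0],
     location_in_parent: [-0.05, -0.09, -0.07], coord_names: [flexion]}
  - {name: hip_l, kind: revolute1, parent: pelvis, child: femur_l, axis: [0.0, 1.0, 0.0],
     location_in_parent: [-0.05, 0.09, -0.07], coord_names: [flexion]}
  - {name: knee_r, kind: revolute1, parent: femur_r, child: tibia_r, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.48], coord_names: [angle]}
  - {name: knee_l, kind: revolute1, parent: femur_l, child: tibia_l, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.48], coord_names: [angle]}
  - {name: ankle_r, kind: revolute1, parent: tibia_r, child: foot_r, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.43], coord_names: [angle]}
  - {name: ankle_l, kind: revolute1, parent: tibia_l, child: foot_l, axis: [0.0, 1.0, 0.0],
     location_in_parent: [0.0, 0.0, -0.43], coord_names: [angle]}
  - {name: binding_r, kind: locked, parent: foot_r, child: ski_r, location_in_parent: [0.03, 0.0, -0.05]}
  - {name: binding_l, kind: locked, parent: foot_l, child: ski_l, location_in_parent: [0.03, 0.0, -0.05]}

planar:
  # coordinate order is the model's canonical order (tree order)
  tracked_angle_channels: [pelvis_pitch, hip_r_flexion, hip_l_flexion, knee_r_angle,
                           knee_l_angle, ankle_r_angle, ankle_l_angle]
  contact_points:
    - {body: ski_r, offset: [-0.55, -0.06], name: tail_r}
    - {body: ski_r, offset: [0.70, -0.06], name: tip_r}
    - {body: ski_l, offset: [-0.55, -0.06], name: tail_l}
    - {body: ski_l, offset: [0.70, -0.06], name: tip_l}

muscle_table: muscles_planar

boot:
  neutral_angle_deg: 14.0     # dorsiflexed neutral: boots hold the shank leaning forward
  deadband_deg: 1.5
  stiffness_linear: 650.0     # stiff alpine race boot
  stiffness_cubic: 9000.0
  damping: 12.0

ski:
  n_segments: 18
  length_m: 1.70
  mass_kg: 3.40
  width_m: 0.07
  camber_height_m: 0.006
  side_cut_radius_m: 18.0
  bend_stiffness: 260.0
  bend_damping: 1.2

snow:
  k_load: 50000.0
  stiffness_ratio: 4.0
  rate_damping: 6000.0
  shear_coefficient: 60000.0
  slope_angle_deg: 12.3

friction:
  mu: 0.08
  slip_epsilon: 0.001

aero:
  cda: 0.3
  rho: 1.07
  wind: [0.0, 0.0, 0.0]

bounds:
  # state/control bounds for the tracking NLP (angles deg, velocities deg/s)
  pelvis_x: [-50.0, 100.0]
  pelvis_z: [-30.0, 30.0]
  pelvis_pitch_deg: [-80.0, 80.0]
  hip_deg: [-60.0, 130.0]
  knee_deg: [-150.0, 5.0]
  ankle_deg: [-40.0, 45.0]
  joint_rate_deg_s: [-1000.0, 1000.0]
  translation_rate: [-40.0, 40.0]
  fiber_length_rel: [0.3, 1.7]   # s bounds as multiples of l_opt*cos(penn_opt)
  activation: [0.0, 1.0]
  excitation: [0.0, 1.0]
  memory_depth: [0.0, 0.5]
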
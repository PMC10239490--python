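# Data-driven three-plane ACL model coefficients.
# SYNTHETIC DEFAULTS: the cadaver-regression coefficient sets this model is
# built around are not published in an extractable form; the values below are
# literature-informed placeholders with the correct qualitative structure
# (sagittal proportion decreasing with flexion; frontal/transverse components
# exponential in the plane moment and decaying with flexion). Absolute ACL
# forces computed with this file are therefore coefficient-dependent.
sagittal_proportion:
  # fraction of the anterior ligamentous shear borne by the ACL, vs knee flexion
  flexion_deg: [0, 15, 30, 45, 60, 75, 90]
  proportion:  [0.85, 0.85, 0.75, 0.55, 0.40, 0.25, 0.15]

frontal:
  scale_n: 20.0        # N
  moment_rate: 0.040   # 1/(N*m), applied to the external abduction moment
  flexion_rate: 1.2    # 1/rad, exponential decay with knee flexion

transverse:
  scale_n: 25.0        # N
  moment_rate: 0.080   # 1/(N*m), applied to the internal-rotation moment
  flexion_rate: 1.0    # 1/rad

patellar_tendon_angle:
  # patellar tendon angle relative to the tibial long axis vs knee flexion;
  # positive = anteriorly directed pull on the tibia (sign change near 70 deg)
  flexion_deg: [0, 20, 40, 60, 70, 90]
  angle_deg:   [20.0, 15.0, 8.0, 2.0, 0.0, -6.0]

knee_muscle_lines:
  # anterior component (unit line of action, tibia frame) of knee-crossing
  # muscle forces acting on the tibia; quadriceps act through the patellar
  # tendon (angle table above)
  hamstrings:       {anterior_component: -0.35}
  gastrocnemius:    {anterior_component: -0.10}
  vasti:            {patellar_tendon: true}
  rectus_femoris:   {patellar_tendon: true}
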
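name,f_max,l_opt,l_slack,penn_opt,tau_act,tau_deact,moment_arms
iliopsoas_r,4500,0.15,0.10,0.14,0.015,0.060,hip_r_flexion:0.060
gluteus_maximus_r,4500,0.2,0.10,0.30,0.015,0.060,hip_r_flexion:-0.060
rectus_femoris_r,1300,0.12,0.35,0.24,0.015,0.060,hip_r_flexion:0.040;knee_r_angle:0.045
vasti_r,9000,0.16,0.22,0.26,0.015,0.060,"knee_r_angle:0.045,0.0,-0.010"
hamstrings_r,4000,0.18,0.30,0.21,0.015,0.060,hip_r_flexion:-0.055;knee_r_angle:-0.035
gastrocnemius_r,2500,0.09,0.38,0.29,0.015,0.060,knee_r_angle:-0.018;ankle_r_angle:-0.050
soleus_r,4500,0.07,0.25,0.49,0.015,0.060,ankle_r_angle:-0.050
tibialis_anterior_r,3200,0.08,0.22,0.17,0.015,0.060,ankle_r_angle:0.045
iliopsoas_l,4500,0.15,0.10,0.14,0.015,0.060,hip_l_flexion:0.060
gluteus_maximus_l,4500,0.2,0.10,0.30,0.015,0.060,hip_l_flexion:-0.060
rectus_femoris_l,1300,0.12,0.35,0.24,0.015,0.060,hip_l_flexion:0.040;knee_l_angle:0.045
vasti_l,9000,0.16,0.22,0.26,0.015,0.060,"knee_l_angle:0.045,0.0,-0.010"
hamstrings_l,4000,0.18,0.30,0.21,0.015,0.060,hip_l_flexion:-0.055;knee_l_angle:-0.035
gastrocnemius_l,2500,0.09,0.38,0.29,0.015,0.060,knee_l_angle:-0.018;ankle_l_angle:-0.050
soleus_l,4500,0.07,0.25,0.49,0.015,0.060,ankle_l_angle:-0.050
tibialis_anterior_l,3200,0.08,0.22,0.17,0.015,0.060,ankle_l_angle:0.045
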
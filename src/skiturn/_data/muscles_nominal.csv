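name,f_max,l_opt,l_slack,penn_opt,tau_act,tau_deact,moment_arms
addbrev_r,430,0.104,0.035,0.11,0.015,0.06,hip_r_adduction:0.03;hip_r_flexion:0.01
addlong_r,627,0.132,0.120,0.14,0.015,0.06,hip_r_adduction:0.035;hip_r_flexion:0.015
addmag_dist_r,324,0.177,0.090,0.16,0.015,0.06,hip_r_adduction:0.04;hip_r_flexion:-0.01
addmag_isch_r,324,0.156,0.221,0.20,0.015,0.06,hip_r_adduction:0.038;hip_r_flexion:-0.02
addmag_mid_r,324,0.138,0.045,0.16,0.015,0.06,hip_r_adduction:0.04
addmag_prox_r,324,0.106,0.040,0.30,0.015,0.06,hip_r_adduction:0.038
bflh_r,705,0.098,0.325,0.20,0.015,0.06,hip_r_flexion:-0.055;knee_r_angle:-0.028
bfsh_r,315,0.110,0.105,0.40,0.015,0.06,knee_r_angle:-0.028
edl_r,345,0.069,0.369,0.19,0.015,0.06,ankle_r_angle:0.035
ehl_r,165,0.075,0.327,0.11,0.015,0.06,ankle_r_angle:0.033
fdl_r,274,0.045,0.378,0.24,0.015,0.06,ankle_r_angle:-0.032
fhl_r,436,0.052,0.354,0.17,0.015,0.06,ankle_r_angle:-0.035
gaslat_r,606,0.059,0.376,0.21,0.015,0.06,knee_r_angle:-0.016;ankle_r_angle:-0.048
gasmed_r,1308,0.051,0.384,0.30,0.015,0.06,knee_r_angle:-0.018;ankle_r_angle:-0.05
gemelli_r,164,0.024,0.039,0.00,0.015,0.06,hip_r_rotation:-0.018
glmax1_r,573,0.147,0.104,0.38,0.015,0.06,hip_r_flexion:-0.05;hip_r_rotation:-0.02
glmax2_r,819,0.157,0.108,0.38,0.015,0.06,hip_r_flexion:-0.062;hip_r_rotation:-0.018
glmax3_r,552,0.167,0.122,0.38,0.015,0.06,hip_r_flexion:-0.06;hip_r_adduction:0.015
glmed1_r,819,0.073,0.056,0.36,0.015,0.06,hip_r_adduction:-0.045;hip_r_flexion:0.01
glmed2_r,573,0.073,0.066,0.36,0.015,0.06,hip_r_adduction:-0.048
glmed3_r,653,0.073,0.046,0.36,0.015,0.06,hip_r_adduction:-0.045;hip_r_flexion:-0.015
glmin1_r,270,0.068,0.016,0.17,0.015,0.06,hip_r_adduction:-0.035;hip_r_rotation:0.01
glmin2_r,285,0.056,0.026,0.17,0.015,0.06,hip_r_adduction:-0.038
glmin3_r,323,0.038,0.051,0.17,0.015,0.06,hip_r_adduction:-0.035;hip_r_rotation:-0.012
grac_r,162,0.228,0.172,0.14,0.015,0.06,hip_r_adduction:0.03;knee_r_angle:-0.018
iliacus_r,1073,0.107,0.096,0.25,0.015,0.06,hip_r_flexion:0.04;hip_r_rotation:0.012
pectineus_r,177,0.133,0.001,0.00,0.015,0.06,hip_r_adduction:0.028;hip_r_flexion:0.02
perbrev_r,348,0.045,0.148,0.20,0.015,0.06,ankle_r_angle:-0.025
perlong_r,943,0.051,0.333,0.25,0.015,0.06,ankle_r_angle:-0.028
piri_r,444,0.026,0.115,0.17,0.015,0.06,hip_r_rotation:-0.022;hip_r_adduction:-0.01
psoas_r,1113,0.117,0.094,0.22,0.015,0.06,hip_r_flexion:0.042
quadfem_r,381,0.054,0.024,0.00,0.015,0.06,hip_r_rotation:-0.02
recfem_r,1169,0.076,0.346,0.24,0.015,0.06,hip_r_flexion:0.04;knee_r_angle:0.045
sart_r,156,0.520,0.124,0.02,0.015,0.06,hip_r_flexion:0.035;knee_r_angle:-0.015
semimem_r,1288,0.069,0.348,0.26,0.015,0.06,hip_r_flexion:-0.055;knee_r_angle:-0.03
semiten_r,410,0.193,0.247,0.22,0.015,0.06,hip_r_flexion:-0.052;knee_r_angle:-0.032
soleus_r,3586,0.044,0.248,0.49,0.015,0.06,ankle_r_angle:-0.05
tfl_r,233,0.095,0.240,0.05,0.015,0.06,hip_r_adduction:-0.04;hip_r_flexion:0.025
tibant_r,674,0.068,0.224,0.17,0.015,0.06,ankle_r_angle:0.04
tibpost_r,1588,0.038,0.281,0.24,0.015,0.06,ankle_r_angle:-0.03
vasint_r,1024,0.099,0.202,0.08,0.015,0.06,knee_r_angle:0.044
vaslat_r,2255,0.099,0.221,0.32,0.015,0.06,knee_r_angle:0.046
vasmed_r,1294,0.097,0.200,0.52,0.015,0.06,knee_r_angle:0.044
addbrev_l,430,0.104,0.035,0.11,0.015,0.06,hip_l_adduction:-0.03;hip_l_flexion:0.01
addlong_l,627,0.132,0.120,0.14,0.015,0.06,hip_l_adduction:-0.035;hip_l_flexion:0.015
addmag_dist_l,324,0.177,0.090,0.16,0.015,0.06,hip_l_adduction:-0.04;hip_l_flexion:-0.01
addmag_isch_l,324,0.156,0.221,0.20,0.015,0.06,hip_l_adduction:-0.038;hip_l_flexion:-0.02
addmag_mid_l,324,0.138,0.045,0.16,0.015,0.06,hip_l_adduction:-0.04
addmag_prox_l,324,0.106,0.040,0.30,0.015,0.06,hip_l_adduction:-0.038
bflh_l,705,0.098,0.325,0.20,0.015,0.06,hip_l_flexion:-0.055;knee_l_angle:-0.028
bfsh_l,315,0.110,0.105,0.40,0.015,0.06,knee_l_angle:-0.028
edl_l,345,0.069,0.369,0.19,0.015,0.06,ankle_l_angle:0.035
ehl_l,165,0.075,0.327,0.11,0.015,0.06,ankle_l_angle:0.033
fdl_l,274,0.045,0.378,0.24,0.015,0.06,ankle_l_angle:-0.032
fhl_l,436,0.052,0.354,0.17,0.015,0.06,ankle_l_angle:-0.035
gaslat_l,606,0.059,0.376,0.21,0.015,0.06,knee_l_angle:-0.016;ankle_l_angle:-0.048
gasmed_l,1308,0.051,0.384,0.30,0.015,0.06,knee_l_angle:-0.018;ankle_l_angle:-0.05
gemelli_l,164,0.024,0.039,0.00,0.015,0.06,hip_l_rotation:0.018
glmax1_l,573,0.147,0.104,0.38,0.015,0.06,hip_l_flexion:-0.05;hip_l_rotation:0.02
glmax2_l,819,0.157,0.108,0.38,0.015,0.06,hip_l_flexion:-0.062;hip_l_rotation:0.018
glmax3_l,552,0.167,0.122,0.38,0.015,0.06,hip_l_flexion:-0.06;hip_l_adduction:-0.015
glmed1_l,819,0.073,0.056,0.36,0.015,0.06,hip_l_adduction:0.045;hip_l_flexion:0.01
glmed2_l,573,0.073,0.066,0.36,0.015,0.06,hip_l_adduction:0.048
glmed3_l,653,0.073,0.046,0.36,0.015,0.06,hip_l_adduction:0.045;hip_l_flexion:-0.015
glmin1_l,270,0.068,0.016,0.17,0.015,0.06,hip_l_adduction:0.035;hip_l_rotation:-0.01
glmin2_l,285,0.056,0.026,0.17,0.015,0.06,hip_l_adduction:0.038
glmin3_l,323,0.038,0.051,0.17,0.015,0.06,hip_l_adduction:0.035;hip_l_rotation:0.012
grac_l,162,0.228,0.172,0.14,0.015,0.06,hip_l_adduction:-0.03;knee_l_angle:-0.018
iliacus_l,1073,0.107,0.096,0.25,0.015,0.06,hip_l_flexion:0.04;hip_l_rotation:-0.012
pectineus_l,177,0.133,0.001,0.00,0.015,0.06,hip_l_adduction:-0.028;hip_l_flexion:0.02
perbrev_l,348,0.045,0.148,0.20,0.015,0.06,ankle_l_angle:-0.025
perlong_l,943,0.051,0.333,0.25,0.015,0.06,ankle_l_angle:-0.028
piri_l,444,0.026,0.115,0.17,0.015,0.06,hip_l_rotation:0.022;hip_l_adduction:0.01
psoas_l,1113,0.117,0.094,0.22,0.015,0.06,hip_l_flexion:0.042
quadfem_l,381,0.054,0.024,0.00,0.015,0.06,hip_l_rotation:0.02
recfem_l,1169,0.076,0.346,0.24,0.015,0.06,hip_l_flexion:0.04;knee_l_angle:0.045
sart_l,156,0.520,0.124,0.02,0.015,0.06,hip_l_flexion:0.035;knee_l_angle:-0.015
semimem_l,1288,0.069,0.348,0.26,0.015,0.06,hip_l_flexion:-0.055;knee_l_angle:-0.03
semiten_l,410,0.193,0.247,0.22,0.015,0.06,hip_l_flexion:-0.052;knee_l_angle:-0.032
soleus_l,3586,0.044,0.248,0.49,0.015,0.06,ankle_l_angle:-0.05
tfl_l,233,0.095,0.240,0.05,0.015,0.06,hip_l_adduction:0.04;hip_l_flexion:0.025
tibant_l,674,0.068,0.224,0.17,0.015,0.06,ankle_l_angle:0.04
tibpost_l,1588,0.038,0.281,0.24,0.015,0.06,ankle_l_angle:-0.03
vasint_l,1024,0.099,0.202,0.08,0.015,0.06,knee_l_angle:0.044
vaslat_l,2255,0.099,0.221,0.32,0.015,0.06,knee_l_angle:0.046
vasmed_l,1294,0.097,0.200,0.52,0.015,0.06,knee_l_angle:0.044
ercspn_r,2500,0.120,0.032,0.00,0.015,0.06,lumbar_extension:0.055;lumbar_bending:-0.03
rectab_r,800,0.300,0.100,0.00,0.015,0.06,lumbar_extension:-0.08
extobl_r,900,0.120,0.140,0.00,0.015,0.06,lumbar_extension:-0.04;lumbar_bending:-0.045;lumbar_rotation:0.03
intobl_r,900,0.100,0.120,0.00,0.015,0.06,lumbar_extension:-0.035;lumbar_bending:-0.045;lumbar_rotation:-0.03
ercspn_l,2500,0.120,0.032,0.00,0.015,0.06,lumbar_extension:0.055;lumbar_bending:0.03
rectab_l,800,0.300,0.100,0.00,0.015,0.06,lumbar_extension:-0.08
extobl_l,900,0.120,0.140,0.00,0.015,0.06,lumbar_extension:-0.04;lumbar_bending:0.045;lumbar_rotation:-0.03
intobl_l,900,0.100,0.120,0.00,0.015,0.06,lumbar_extension:-0.035;lumbar_bending:0.045;lumbar_rotation:0.03
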
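# Generic trunk-muscle roster, right side (y < 0); the builder mirrors rows to the left side.
# Local coordinates (m) in the owning body's frame for the default 1.78 m geometry; scaled uniformly with stature.
# PCSA in cm^2 per thread, m_ratio = fibre/MTU length ratio. Values are literature-plausible desk-scale
# defaults (editable); the full published roster can be dropped in by extending this table.
name,group,origin_body,origin_x,origin_y,origin_z,via1_body,via1_x,via1_y,via1_z,via2_body,via2_x,via2_y,via2_z,insertion_body,insertion_x,insertion_y,insertion_z,PCSA_cm2,m_ratio
RA,abdominal,pelvis,0.090,-0.040,0.050,,,,,,,,,linea_alba,0.005,-0.035,0.100,12.0,0.70
EO,abdominal,linea_alba,0.000,-0.050,0.020,,,,,,,,,T10,0.020,-0.090,0.000,10.0,0.60
EO_T8,abdominal,linea_alba,0.000,-0.048,0.060,,,,,,,,,T8,0.020,-0.085,0.000,5.0,0.60
EO_T6,abdominal,linea_alba,0.000,-0.045,0.090,,,,,,,,,T6,0.020,-0.080,0.000,5.0,0.60
IO,abdominal,pelvis,0.040,-0.090,0.060,,,,,,,,,linea_alba,0.000,-0.045,0.060,16.0,0.60
PM_L1,abdominal,pelvis,0.050,-0.050,0.020,,,,,,,,,L1,0.015,-0.030,0.000,5.0,0.45
PM_L2,abdominal,pelvis,0.050,-0.050,0.020,,,,,,,,,L2,0.015,-0.030,0.000,5.0,0.45
PM_L3,abdominal,pelvis,0.050,-0.050,0.020,,,,,,,,,L3,0.015,-0.030,0.000,5.0,0.45
PM_L4,abdominal,pelvis,0.050,-0.050,0.020,,,,,,,,,L4,0.015,-0.030,0.000,5.0,0.45
PM_L5,abdominal,pelvis,0.050,-0.050,0.020,,,,,,,,,L5,0.015,-0.030,0.000,5.0,0.45
LT_lum,back,pelvis,-0.050,-0.040,0.030,L3,-0.050,-0.035,0.000,,,,,T12,-0.040,-0.030,0.000,32.0,0.60
LT_tho,back,pelvis,-0.050,-0.030,0.040,L1,-0.055,-0.040,0.000,T8,-0.050,-0.040,0.000,T2,-0.040,-0.030,0.000,40.0,0.45
IC_lum,back,pelvis,-0.045,-0.060,0.030,L3,-0.050,-0.055,0.000,,,,,T12,-0.045,-0.060,0.000,24.0,0.60
IC_tho,back,pelvis,-0.040,-0.065,0.040,L1,-0.050,-0.060,0.000,T9,-0.045,-0.065,0.000,T5,-0.035,-0.050,0.000,28.0,0.45
IT_L5,back,L5,-0.005,-0.035,0.010,,,,,,,,,L4,-0.005,-0.035,-0.008,0.6,0.80
IT_L4,back,L4,-0.005,-0.035,0.010,,,,,,,,,L3,-0.005,-0.035,-0.008,0.6,0.80
IT_L3,back,L3,-0.005,-0.035,0.010,,,,,,,,,L2,-0.005,-0.035,-0.008,0.6,0.80
IT_L2,back,L2,-0.005,-0.035,0.010,,,,,,,,,L1,-0.005,-0.035,-0.008,0.6,0.80
IT_L1,back,L1,-0.005,-0.035,0.010,,,,,,,,,T12,-0.005,-0.035,-0.008,0.6,0.80
MF_S1,back,S1,-0.040,-0.010,0.010,,,,,,,,,L3,-0.030,-0.020,0.000,6.0,0.65
MF_L5,back,L5,-0.050,-0.008,0.000,,,,,,,,,L2,-0.030,-0.020,0.000,6.0,0.65
MF_L4,back,L4,-0.050,-0.008,0.000,,,,,,,,,L1,-0.030,-0.020,0.000,6.0,0.65
MF_L3,back,L3,-0.050,-0.008,0.000,,,,,,,,,T12,-0.030,-0.020,0.000,6.0,0.65
MF_L2,back,L2,-0.050,-0.008,0.000,,,,,,,,,T11,-0.028,-0.018,0.000,6.0,0.65
SP_tho,back,T12,-0.050,-0.005,0.000,T7,-0.045,-0.008,0.000,,,,,T2,-0.040,-0.005,0.000,6.0,0.40
SP_lum,back,L1,-0.055,-0.005,0.000,T9,-0.048,-0.008,0.000,,,,,T6,-0.040,-0.005,0.000,5.0,0.40
MF_T3,back,T3,-0.045,-0.006,0.000,,,,,,,,,T1,-0.028,-0.015,0.000,2.5,0.60
MF_T4,back,T4,-0.045,-0.006,0.000,,,,,,,,,T2,-0.028,-0.015,0.000,2.5,0.60
MF_T5,back,T5,-0.045,-0.006,0.000,,,,,,,,,T3,-0.028,-0.015,0.000,2.5,0.60
MF_T6,back,T6,-0.045,-0.006,0.000,,,,,,,,,T4,-0.028,-0.015,0.000,2.5,0.60
MF_T7,back,T7,-0.045,-0.006,0.000,,,,,,,,,T5,-0.028,-0.015,0.000,2.5,0.60
MF_T8,back,T8,-0.045,-0.006,0.000,,,,,,,,,T6,-0.028,-0.015,0.000,2.5,0.60
MF_T9,back,T9,-0.045,-0.006,0.000,,,,,,,,,T7,-0.028,-0.015,0.000,2.5,0.60
MF_T10,back,T10,-0.045,-0.006,0.000,,,,,,,,,T8,-0.028,-0.015,0.000,2.5,0.60
MF_T11,back,T11,-0.045,-0.006,0.000,,,,,,,,,T9,-0.028,-0.015,0.000,2.5,0.60
MF_T12,back,T12,-0.045,-0.006,0.000,,,,,,,,,T10,-0.028,-0.015,0.000,2.5,0.60
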
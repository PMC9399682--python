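feature_id,atlas_index,short_name,hemisphere,property,w,abs_ln_abs_w,rank
lh_S_occipital_ant_FD,59,S_occipital_ant,left,FD,2.906e-5,10.446,1
rh_G_oc-temp_med-Parahip_GI,23,G_oc-temp_med-Parahip,right,GI,-3.70e-5,10.204,2
rh_G_cingul-Post-ventral_GI,10,G_cingul-Post-ventral,right,GI,4.792e-5,9.946,3
lh_S_oc-temp_med_and_Lingual_GI,61,S_oc-temp_med_and_Lingual,left,GI,1.191e-4,9.035,4
rh_S_circular_insula_inf_FD,48,S_circular_insula_inf,right,FD,-1.220e-4,9.011,5
lh_G_temp_sup-Lateral_FD,34,G_temp_sup-Lateral,left,FD,1.362e-4,8.901,6
rh_S_oc_sup_and_transversal_FD,58,S_oc_sup_and_transversal,right,FD,2.724e-4,8.208,7
lh_G_cingul-Post-dorsal_FD,9,G_cingul-Post-dorsal,left,FD,2.95e-4,8.128,8
lh_S_orbital-H_Shaped_CTh,64,S_orbital-H_Shaped,left,CTh,-3.028e-4,8.102,9
rh_G_pariet_inf-Angular_CTh,25,G_pariet_inf-Angular,right,CTh,3.828e-4,7.868,10
lh_G_front_inf-Orbital_CTh,13,G_front_inf-Orbital,left,CTh,-4.306e-4,7.750,11
lh_G_temp_sup-Plan_polar_GI,35,G_temp_sup-Plan_polar,left,GI,5.301e-4,7.543,12
rh_G_temp_sup-Plan_polar_GI,35,G_temp_sup-Plan_polar,right,GI,6.002e-4,7.418,13
lh_S_precentral-sup-part_FD,69,S_precentral-sup-part,left,FD,6.093e-4,7.403,14
rh_Pole_occipital_SD,42,Pole_occipital,right,SD,6.576e-4,7.327,15
rh_G_cingul-Post-dorsal_CTh,9,G_cingul-Post-dorsal,right,CTh,6.672e-4,7.312,16
rh_Lat_Fis-post_GI,41,Lat_Fis-post,right,GI,7.468e-4,7.200,17
lh_G_Ins_lg_and_S_cent_ins_FD,17,G_Ins_lg_and_S_cent_ins,left,FD,7.729e-4,7.165,18
rh_Pole_temporal_GI,43,Pole_temporal,right,GI,-8.033e-4,7.127,19
rh_S_circular_insula_sup_FD,49,S_circular_insula_sup,right,FD,8.454e-4,7.076,20
lh_G_oc-temp_med-Parahip_CTh,23,G_oc-temp_med-Parahip,left,CTh,9.782e-4,6.930,21
rh_S_occipital_ant_FD,59,S_occipital_ant,right,FD,1.063e-3,6.846,22
lh_S_circular_insula_sup_FD,49,S_circular_insula_sup,left,FD,1.101e-3,6.812,23
lh_S_temporal_sup_CTh,73,S_temporal_sup,left,CTh,1.218e-3,6.711,24
lh_G_pariet_inf-Angular_CTh,25,G_pariet_inf-Angular,left,CTh,1.237e-3,6.695,25
lh_S_circular_insula_sup_GI,49,S_circular_insula_sup,left,GI,1.407e-3,6.566,26
lh_S_temporal_sup_FD,73,S_temporal_sup,left,FD,1.506e-3,6.498,27
lh_S_circular_insula_inf_GI,48,S_circular_insula_inf,left,GI,1.507e-3,6.497,28
lh_Lat_Fis-post_SD,41,Lat_Fis-post,left,SD,1.681e-3,6.388,29
rh_S_oc-temp_lat_FD,60,S_oc-temp_lat,right,FD,1.707e-3,6.373,30
rh_S_temporal_sup_FD,73,S_temporal_sup,right,FD,2.041e-3,6.194,31
lh_G_cingul-Post-dorsal_CTh,9,G_cingul-Post-dorsal,left,CTh,2.12e-3,6.158,32
rh_G_and_S_cingul-Mid-Ant_SD,7,G_and_S_cingul-Mid-Ant,right,SD,-2.651e-3,5.933,33
rh_S_circular_insula_sup_GI,49,S_circular_insula_sup,right,GI,2.718e-3,5.908,34
rh_S_circular_insula_inf_GI,48,S_circular_insula_inf,right,GI,2.775e-3,5.887,35
rh_S_temporal_sup_SD,73,S_temporal_sup,right,SD,3.006e-3,5.807,36
rh_G_oc-temp_med-Parahip_CTh,23,G_oc-temp_med-Parahip,right,CTh,3.16e-3,5.758,37
lh_S_cingul-Marginalis_FD,46,S_cingul-Marginalis,left,FD,3.597e-3,5.628,38
lh_S_temporal_sup_SD,73,S_temporal_sup,left,SD,3.923e-3,5.541,39
rh_G_and_S_cingul-Ant_SD,6,G_and_S_cingul-Ant,right,SD,-4.038e-3,5.512,40
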
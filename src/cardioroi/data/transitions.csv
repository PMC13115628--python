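from_state,to_state,annual_prob,dist_family,dist_a,dist_b,derivation_flag
healthy,obesity,0.0246,beta,50,950,literature
healthy,pre_dm,0.0224,beta,20,980,literature
healthy,pre_htn,0.0037,beta,30,970,literature
obesity,pre_dm,0.0381,beta,80,920,literature
obesity,dm,0.0164,beta,30,970,literature
pre_dm,dm,0.0112,beta,70,930,literature
pre_dm,hr_dm,0.0044,beta,10,990,derived
pre_htn,htn,0.0041,beta,50,950,literature
htn,htn2,0.0025,beta,20,980,derived
dm,hr_dm,0.0131,beta,30,970,literature
dm_htn,hr_dm,0.0157,beta,40,960,derived
ANY,cad,0.0016,beta,10,990,literature
ANY,mi,0.0010,beta,50,950,literature
ANY,chf,0.0026,beta,20,980,literature
ANY,stroke,0.0020,beta,10,990,literature
ob_htn,ob_htn_dm,0.0004,beta,0.4,999.6,calibrated
ob_dm,ob_htn_dm,0.0004,beta,0.4,999.6,calibrated
ob_htn_dm,hr_dm,0.0004,beta,0.4,999.6,calibrated
ANY,DEATH,,fixed,0,0,age_specific
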
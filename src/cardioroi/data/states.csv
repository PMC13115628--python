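state_id,label,annual_cost_usd,utility,cost_dist_family,cost_a,cost_b,utility_dist_family,utility_a,utility_b,reversible
healthy,Healthy,0,1,gamma,100,0,beta,17.1,0.9,False
obesity,Obesity,1200,0.88,gamma,100,12,beta,880,120,True
pre_dm,Pre-Diabetes,3000,0.87,gamma,100,30,beta,87,13,False
pre_htn,Pre-Hypertension,1000,0.86,gamma,100,10,beta,86,14,False
htn,Hypertension (HTN),2500,0.85,gamma,100,25,beta,850,150,True
htn2,HTN Stage 2,4000,0.8,gamma,100,40,beta,80,20,False
dm,Diabetes (DM),9500,0.7,gamma,100,95,beta,70,30,True
cad,Ischemic Heart Disease (CAD),12000,0.78,gamma,100,120,beta,780,220,False
mi,Myocardial Infarction (MI),20000,0.75,gamma,100,200,beta,75,25,False
chf,Congestive Heart Failure (CHF),14000,0.68,gamma,100,140,beta,68,32,False
stroke,Stroke,12000,0.6,gamma,100,120,beta,60,40,False
dm_htn,DM + HTN,11000,0.6,gamma,100,110,beta,60,40,False
ob_htn,Obesity + HTN,3200,0.75,gamma,100,32,beta,75,25,False
ob_dm,Obesity + DM,10700,0.62,gamma,100,107,beta,62,38,False
ob_htn_dm,Obesity + HTN + DM,12500,0.55,gamma,100,125,beta,55,45,False
hr_dm,High-Risk Diabetes,14500,0.55,gamma,100,145,beta,55,45,False
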
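parameter_id,arm,category,source_state,target_state,mean,sd,distribution
tp_icd_hosp_to_well,icd,transition,hospitalization,well,0.822,,fixed
tp_icd_hosp_to_death,icd,transition,hospitalization,death,0.178,0.008,beta
tp_icd_compl_to_well,icd,transition,complication,well,0.768,,fixed
tp_icd_compl_to_rejection,icd,transition,complication,rejection,0.022,,fixed
tp_icd_compl_to_death,icd,transition,complication,death,0.21,0.109,beta
tp_icd_rej_to_well,icd,transition,rejection,well,0.822,,fixed
tp_icd_rej_to_death,icd,transition,rejection,death,0.178,0.008,beta
tp_pharm_hosp_to_well,pharm,transition,hospitalization,well,0.716,,fixed
tp_pharm_hosp_to_death,pharm,transition,hospitalization,death,0.284,0.009,beta
tp_icd_well_to_hosp,icd,transition,well,hospitalization,0.0,,fixed
tp_icd_well_to_compl,icd,transition,well,complication,0.13370649001838975,,fixed
tp_icd_well_to_death,icd,transition,well,death,0.0,,fixed
tp_pharm_well_to_hosp,pharm,transition,well,hospitalization,0.1177247494855285,,fixed
tp_pharm_well_to_death,pharm,transition,well,death,0.0,,fixed
cost_icd_well,icd,cost,well,,3398.0,1105.0,gamma
cost_icd_compl,icd,cost,complication,,3221.0,933.0,gamma
cost_icd_hosp,icd,cost,hospitalization,,2925.0,1247.0,gamma
cost_icd_death,icd,cost,death,,2777.0,,fixed
cost_pharm_well,pharm,cost,well,,741.0,1246.0,gamma
cost_pharm_hosp,pharm,cost,hospitalization,,1465.0,2024.0,gamma
cost_pharm_death,pharm,cost,death,,467.0,,fixed
util_icd_well,icd,utility,well,,0.845,0.124,beta
util_icd_compl,icd,utility,complication,,0.75,,fixed
util_icd_hosp,icd,utility,hospitalization,,0.725,,fixed
util_pharm_well,pharm,utility,well,,0.88,0.1,beta
util_pharm_hosp,pharm,utility,hospitalization,,0.85,,fixed
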
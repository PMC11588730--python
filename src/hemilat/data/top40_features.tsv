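family	roi_id	roi_name	score
LFunctionCorrR	142	17Networks_LH_ContB_PFClv_3	1.7264
LFunctionCorrR	247	17Networks_RH_SomMotB_S2_1	1.3565
LFunctionCorrR	141	17Networks_LH_ContB_PFClv_2	1.0716
LFunctionCorrR	202	17Networks_RH_VisCent_ExStr_2	0.8601
LFunctionCorrR	135	17Networks_LH_ContB_Temp_2	0.8327
LFunctionCorrR	214	17Networks_RH_VisPeri_ExStrInf_2	0.6181
LFunctionCorrR	296	17Networks_RH_SalVentAttnA_FrMed_1	0.5476
LFunctionCorrR	27	17Networks_LH_SomMotA_3	0.5246
LFunctionCorrR	238	17Networks_RH_SomMotA_15	0.5245
LFunctionCorrR	248	17Networks_RH_SomMotB_S2_2	0.4667
LFunctionCorrR	260	17Networks_RH_DorsAttnA_TempOcc_2	0.4587
LBetweennessCentralityR	3	17Networks_LH_VisCent_ExStr_3	3.2555
LBetweennessCentralityR	253	17Networks_RH_SomMotB_S2_6	0.9084
LBetweennessCentralityR	194	17Networks_LH_DefaultC_PHC_3	0.8993
LBetweennessCentralityR	114	17Networks_LH_LimbicA_TempPole_1	0.8909
LBetweennessCentralityR	251	17Networks_RH_SomMotB_S2_4	0.6140
LBetweennessCentralityR	238	17Networks_RH_SomMotA_15	0.5774
LBetweennessCentralityR	25	17Networks_LH_SomMotA_1	0.5479
LDegreeR	116	17Networks_LH_LimbicA_TempPole_3	3.3489
LDegreeR	174	17Networks_LH_DefaultB_IPL_2	1.7879
LDegreeR	102	17Networks_LH_SalVentAttnB_PFCl_2	1.6415
LDegreeR	320	17Networks_RH_LimbicA_TempPole_2	1.1336
LDegreeR	173	17Networks_LH_DefaultB_IPL_1	0.9373
LDegreeR	336	17Networks_RH_ContB_Temp_1	0.8544
LDegreeR	239	17Networks_RH_SomMotA_16	0.6139
LDegreeR	235	17Networks_RH_SomMotA_12	0.5771
LDegreeR	14	17Networks_LH_VisPeri_ExStrInf_2	0.5367
LDegreeR	379	17Networks_RH_DefaultB_PFCd_3	0.5315
LDegreeR	305	17Networks_RH_SalVentAttnB_PFClv_1	0.5228
LDegreeR	161	17Networks_LH_DefaultA_PFCm_1	0.5200
LDegreeR	237	17Networks_RH_SomMotA_14	0.4673
LStrengthR	116	17Networks_LH_LimbicA_TempPole_3	3.4086
LStrengthR	336	17Networks_RH_ContB_Temp_1	2.5139
LStrengthR	379	17Networks_RH_DefaultB_PFCd_3	1.2896
LStrengthR	173	17Networks_LH_DefaultB_IPL_1	1.2728
LStrengthR	14	17Networks_LH_VisPeri_ExStrInf_2	0.8061
LStrengthR	238	17Networks_RH_SomMotA_15	0.7600
LStrengthR	239	17Networks_RH_SomMotA_16	0.7409
LStrengthR	161	17Networks_LH_DefaultA_PFCm_1	0.6164
LStrengthR	135	17Networks_LH_ContB_Temp_2	0.5499
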
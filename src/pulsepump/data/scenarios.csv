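organ_system,condition,flow_rate_ml_min,flow_sd_ml_min,beat_rate_bpm,systole_time_s,ref
fingertip,post-caffeine,0.029,0.004,71,0.1,PP
retinal,baseline,0.033,,70,0.1,LD
fingertip,venous occlusion (lower),0.056,,70,0.1,VOP
fingertip,pre-caffeine,0.067,0.009,74,0.1,PP
retinal,baseline (flux),0.08,0.012,70,0.1,LD
fingertip,baseline,0.088,0.015,76,0.1,PP
fingertip,venous occlusion (critical),0.2,,70,0.1,VOP
retinal,baseline (MRI),0.261,0.087,70,0.1,PC-MRI
fingertip,venous occlusion (upper),0.42,,70,0.1,VOP
ocular,total pulsatile (lower),0.444,,70,0.1,PC-MRI
splenic (rat),pre-caudal ligation,0.6,0.1,380,0.054,TTP
splenic (rat),pre-rostral ligation,0.8,0.3,380,0.054,TTP
ocular,total pulsatile (upper),0.803,,70,0.1,PC-MRI
choroidal,baseline,0.917,0.281,70,0.1,PC-MRI
ocular,baseline (pneumotonometer),1,,70,0.1,LP
splenic (rat),post-caudal ligation,1.0,0.2,380,0.054,TTP
splenic (rat),post-rostral ligation,1.2,0.1,380,0.054,TTP
middle meningeal artery,baseline,6,3,70,0.1,PC-MRI
ophthalmic artery,baseline,11,5,70,0.1,PC-MRI
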
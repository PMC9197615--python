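cohort,primary_lateral,primary_medial,s_lateral_medial,s_medial_lateral
modern,19,4,23,0
initial_early_jomon,0,3,0,7
late_jomon,0,0,1,4
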
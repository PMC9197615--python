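specimen_id,period_label,c14_age_bp,c14_err_bp,cal_bp_from,cal_bp_to,probability_pct
1,Late Jomon,3928,28,4419,4352,46.0
1,Late Jomon,3928,28,4329,4298,22.3
2,Late Jomon,3757,23,4217,4211,3.3
2,Late Jomon,3757,23,4153,4086,65.0
3,Late Jomon,3807,23,4236,4194,36.6
3,Late Jomon,3807,23,4188,4152,31.6
4,Late Jomon,3913,29,4414,4350,43.8
4,Late Jomon,3913,29,4331,4296,24.4
6,Late Jomon,3890,23,4405,4345,39.7
6,Late Jomon,3890,23,4338,4293,28.5
16,Early Jomon,5925,25,6787,6730,53.0
16,Early Jomon,5925,25,6698,6679,15.2
19,Early Jomon,6285,31,7256,7192,55.6
19,Early Jomon,6285,31,7180,7166,12.6
29,Early Jomon,6286,33,7256,7231,22.7
29,Early Jomon,6286,33,7225,7190,31.1
29,Early Jomon,6286,33,7183,7166,14.5
35,Early Jomon,6667,33,7578,7557,22.5
35,Early Jomon,6667,33,7545,7508,45.7
39,Early Jomon,6524,32,7480,7421,56.8
39,Early Jomon,6524,32,7380,7361,11.5
40,Early Jomon,6382,31,7411,7402,6.4
40,Early Jomon,6382,31,7325,7264,61.9
46,Early Jomon,5864,39,6738,6648,68.3
56,Initial Jomon,8926,30,10183,10120,31.3
56,Initial Jomon,8926,30,10064,10037,13.4
56,Initial Jomon,8926,30,10028,10010,7.4
56,Initial Jomon,8926,30,9991,9960,16.2
59,Initial Jomon,8564,51,9550,9488,68.3
60,Early Jomon,6514,39,7473,7444,21.1
60,Early Jomon,6514,39,7434,7420,14.2
60,Early Jomon,6514,39,7383,7335,33.0
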
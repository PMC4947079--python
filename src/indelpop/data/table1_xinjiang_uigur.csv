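locus,rs_id,cytoband,dip_plus,dip_minus,mp,pd,pic,pe,tpi,ho,he,hwe_p,n
HLD61,1610905,16q13,0.5184,0.4816,0.3539,0.6461,0.3747,0.1463,0.9067,0.4485,0.5030,0.2196,136
HLD39,17878444,1p22.1,0.2978,0.7022,0.4303,0.5697,0.3308,0.1359,0.8831,0.4338,0.4213,0.7398,136
HLD40,2307956,1p32.3,0.5515,0.4485,0.3803,0.6197,0.3723,0.1875,1.0000,0.5000,0.4984,0.9354,136
HLD45,2307959,2q31.1,0.6066,0.3934,0.3874,0.6126,0.3634,0.1689,0.9577,0.4779,0.4808,0.9798,136
HLD48,28369942,2q11.2,0.4007,0.5993,0.3729,0.6271,0.3650,0.1463,0.9067,0.4485,0.4839,0.4338,136
HLD56,2308292,4q25,0.6581,0.3419,0.3859,0.6141,0.3488,0.0994,0.8000,0.3750,0.4533,0.0724,136
HLD58,1610937,5q14.1,0.4154,0.5846,0.3729,0.6271,0.3677,0.1573,0.9315,0.4632,0.4893,0.5714,136
HLD64,1610935,5q12.3,0.7206,0.2794,0.4437,0.5563,0.3216,0.1308,0.8718,0.4265,0.4057,0.5961,136
HLD67,1305056,5q33.2,0.6140,0.3860,0.4047,0.5953,0.3617,0.1940,1.0149,0.5074,0.4775,0.4608,136
HLD70,2307652,6q16.1,0.5699,0.4301,0.3965,0.6035,0.3701,0.2075,1.0462,0.5221,0.4939,0.4839,136
HLD77,1611048,7q31.1,0.4890,0.5110,0.3716,0.6284,0.3749,0.1811,0.9855,0.4926,0.5035,0.8346,136
HLD81,17879936,7q21.3,0.6471,0.3529,0.3991,0.6009,0.3524,0.1517,0.9189,0.4559,0.4601,0.9524,136
HLD83,2308072,8p22,0.3640,0.6360,0.4417,0.5583,0.3558,0.2366,1.1148,0.5515,0.4664,0.0425,136
HLD84,3081400,8q24.12,0.6213,0.3787,0.3654,0.6346,0.3598,0.0994,0.8000,0.3750,0.4740,0.0230,136
HLD88,8190570,9q22.32,0.4632,0.5368,0.3854,0.6146,0.3736,0.2007,1.0303,0.5147,0.5010,0.7164,136
HLD92,17174476,11q22.2,0.4816,0.5184,0.4054,0.5946,0.3747,0.2366,1.1148,0.5515,0.5030,0.2407,136
HLD93,2307570,12q22,0.5257,0.4743,0.3881,0.6119,0.3743,0.2075,1.0462,0.5221,0.5024,0.6153,136
HLD97,17238892,13q12.3,0.3382,0.6618,0.3949,0.6051,0.3475,0.1212,0.8500,0.4118,0.4510,0.3787,136
HLD99,2308163,14q23.1,0.6801,0.3199,0.4181,0.5819,0.3404,0.1463,0.9067,0.4485,0.4383,0.7809,136
HLD101,2307433,15q26.1,0.5000,0.5000,0.3616,0.6384,0.3750,0.1630,0.9444,0.4706,0.5037,0.4660,136
HLD111,1305047,17p11.2,0.3346,0.6654,0.4080,0.5920,0.3461,0.1463,0.9067,0.4485,0.4486,0.9695,136
HLD114,2307581,17p13.3,0.3199,0.6801,0.4134,0.5866,0.3404,0.1359,0.8831,0.4338,0.4383,0.9461,136
HLD118,16438,20p11.1,0.6066,0.3934,0.3941,0.6059,0.3634,0.1811,0.9855,0.4926,0.4808,0.7505,136
HLD122,8178524,21q22.11,0.4485,0.5515,0.3803,0.6197,0.3723,0.1875,1.0000,0.5000,0.4984,0.9354,136
HLD124,6481,22q12.3,0.6360,0.3640,0.3902,0.6098,0.3558,0.1463,0.9067,0.4485,0.4664,0.7053,136
HLD125,16388,22q11.23,0.4890,0.5110,0.3487,0.6513,0.3749,0.1359,0.8831,0.4338,0.5035,0.1139,136
HLD128,2307924,1q31.3,0.4338,0.5662,0.4087,0.5913,0.3706,0.2291,1.0968,0.5441,0.4949,0.2336,136
HLD131,1611001,7q36.2,0.4890,0.5110,0.4050,0.5950,0.3749,0.2366,1.1148,0.5515,0.5035,0.2448,136
HLD133,2067235,3p22.1,0.4449,0.5551,0.3848,0.6152,0.3719,0.1940,1.0149,0.5074,0.4976,0.7865,136
HLD136,16363,22q13.1,0.4779,0.5221,0.3689,0.6311,0.3745,0.1750,0.9714,0.4853,0.5027,0.7164,136
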
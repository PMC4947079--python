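population,Beijing Han,Guangdong Han,Shanghai Han,Yi,Xibe,South Korean,Tibetan,She,Kazak,Urumchi Uigur,Dane,Hungarian,Basque,Central Spanish,Uruguayan,Chihuahua Mexican,Jalisco Mexican,Mexico Mexican,Veracruz Mexican,Yucatan Mexican,Mexican Amerindian,Xinjiang Uigur
Beijing Han,0.0000,0.0019,0.0011,0.0054,0.0022,0.0024,0.0029,0.0023,0.0083,0.0100,0.0251,0.0255,0.0270,0.0262,0.0230,0.0445,0.0437,0.0534,0.0498,0.0588,0.0718,0.0101
Guangdong Han,0.0019,0.0000,0.0006,0.0038,0.0023,0.0017,0.0055,0.0015,0.0100,0.0118,0.0265,0.0275,0.0268,0.0269,0.0244,0.0471,0.0450,0.0548,0.0500,0.0599,0.0724,0.0115
Shanghai Han,0.0011,0.0006,0.0000,0.0040,0.0015,0.0008,0.0038,0.0019,0.0096,0.0114,0.0264,0.0271,0.0270,0.0268,0.0240,0.0465,0.0448,0.0544,0.0502,0.0598,0.0732,0.0108
Yi,0.0054,0.0038,0.0040,0.0000,0.0052,0.0042,0.0066,0.0051,0.0133,0.0163,0.0315,0.0325,0.0328,0.0323,0.0286,0.0522,0.0512,0.0602,0.0566,0.0675,0.0798,0.0156
Xibe,0.0022,0.0023,0.0015,0.0052,0.0000,0.0016,0.0037,0.0032,0.0068,0.0092,0.0227,0.0231,0.0236,0.0226,0.0203,0.0441,0.0420,0.0517,0.0473,0.0569,0.0698,0.0088
South Korean,0.0024,0.0017,0.0008,0.0042,0.0016,0.0000,0.0038,0.0028,0.0115,0.0135,0.0288,0.0295,0.0287,0.0288,0.0258,0.0500,0.0484,0.0576,0.0535,0.0633,0.0770,0.0125
Tibetan,0.0029,0.0055,0.0038,0.0066,0.0037,0.0038,0.0000,0.0065,0.0074,0.0093,0.0226,0.0222,0.0258,0.0231,0.0199,0.0422,0.0417,0.0502,0.0468,0.0567,0.0698,0.0086
She,0.0023,0.0015,0.0019,0.0051,0.0032,0.0028,0.0065,0.0000,0.0112,0.0133,0.0275,0.0289,0.0288,0.0285,0.0255,0.0525,0.0502,0.0606,0.0555,0.0655,0.0796,0.0127
Kazak,0.0083,0.0100,0.0096,0.0133,0.0068,0.0115,0.0074,0.0112,0.0000,0.0013,0.0093,0.0084,0.0111,0.0085,0.0067,0.0278,0.0260,0.0345,0.0301,0.0391,0.0519,0.0019
Urumchi Uigur,0.0100,0.0118,0.0114,0.0163,0.0092,0.0135,0.0093,0.0133,0.0013,0.0000,0.0083,0.0068,0.0096,0.0069,0.0057,0.0241,0.0225,0.0313,0.0263,0.0351,0.0477,0.0012
Dane,0.0251,0.0265,0.0264,0.0315,0.0227,0.0288,0.0226,0.0275,0.0093,0.0083,0.0000,0.0026,0.0048,0.0030,0.0039,0.0183,0.0170,0.0222,0.0192,0.0267,0.0365,0.0073
Hungarian,0.0255,0.0275,0.0271,0.0325,0.0231,0.0295,0.0222,0.0289,0.0084,0.0068,0.0026,0.0000,0.0045,0.0022,0.0021,0.0156,0.0137,0.0210,0.0160,0.0230,0.0317,0.0055
Basque,0.0270,0.0268,0.0270,0.0328,0.0236,0.0287,0.0258,0.0288,0.0111,0.0096,0.0048,0.0045,0.0000,0.0033,0.0043,0.0212,0.0197,0.0256,0.0209,0.0277,0.0389,0.0090
Central Spanish,0.0262,0.0269,0.0268,0.0323,0.0226,0.0288,0.0231,0.0285,0.0085,0.0069,0.0030,0.0022,0.0033,0.0000,0.0023,0.0200,0.0181,0.0258,0.0197,0.0279,0.0393,0.0062
Uruguayan,0.0230,0.0244,0.0240,0.0286,0.0203,0.0258,0.0199,0.0255,0.0067,0.0057,0.0039,0.0021,0.0043,0.0023,0.0000,0.0207,0.0189,0.0274,0.0223,0.0300,0.0427,0.0051
Chihuahua Mexican,0.0445,0.0471,0.0465,0.0522,0.0441,0.0500,0.0422,0.0525,0.0278,0.0241,0.0183,0.0156,0.0212,0.0200,0.0207,0.0000,0.0017,0.0048,0.0040,0.0048,0.0093,0.0246
Jalisco Mexican,0.0437,0.0450,0.0448,0.0512,0.0420,0.0484,0.0417,0.0502,0.0260,0.0225,0.0170,0.0137,0.0197,0.0181,0.0189,0.0017,0.0000,0.0041,0.0024,0.0046,0.0090,0.0226
Mexico Mexican,0.0534,0.0548,0.0544,0.0602,0.0517,0.0576,0.0502,0.0606,0.0345,0.0313,0.0222,0.0210,0.0256,0.0258,0.0274,0.0048,0.0041,0.0000,0.0030,0.0041,0.0087,0.0310
Veracruz Mexican,0.0498,0.0500,0.0502,0.0566,0.0473,0.0535,0.0468,0.0555,0.0301,0.0263,0.0192,0.0160,0.0209,0.0197,0.0223,0.0040,0.0024,0.0030,0.0000,0.0031,0.0064,0.0262
Yucatan Mexican,0.0588,0.0599,0.0598,0.0675,0.0569,0.0633,0.0567,0.0655,0.0391,0.0351,0.0267,0.0230,0.0277,0.0279,0.0300,0.0048,0.0046,0.0041,0.0031,0.0000,0.0053,0.0353
Mexican Amerindian,0.0718,0.0724,0.0732,0.0798,0.0698,0.0770,0.0698,0.0796,0.0519,0.0477,0.0365,0.0317,0.0389,0.0393,0.0427,0.0093,0.0090,0.0087,0.0064,0.0053,0.0000,0.0473
Xinjiang Uigur,0.0101,0.0115,0.0108,0.0156,0.0088,0.0125,0.0086,0.0127,0.0019,0.0012,0.0073,0.0055,0.0090,0.0062,0.0051,0.0246,0.0226,0.0310,0.0262,0.0353,0.0473,0.0000
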
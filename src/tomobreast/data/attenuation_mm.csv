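energy_keV,Al,PMMA,Rh,a-Se,adipose,breast_50_50,calcium,glandular
5.25,45.4515,2.7082,755.649,157.913,2.02546,2.41125,75.8104,2.81914
5.75,35.1129,2.06496,585.787,121.312,1.54425,1.84046,58.8992,2.15368
6.25,27.6661,1.61073,463.858,95.2677,1.20454,1.43704,46.7344,1.6829
6.75,22.1636,1.28086,373.969,76.2201,0.957905,1.14382,37.7485,1.34044
7.25,18.0392,1.03552,306.178,61.9611,0.77451,0.925567,30.9595,1.08533
7.75,14.8854,0.849261,254.043,51.0705,0.635311,0.759755,25.7295,0.89138
8.25,12.4165,0.705479,213.26,42.606,0.52796,0.631339,22.0298,0.740683
8.75,10.4561,0.592708,180.878,35.9256,0.443833,0.530338,19.3749,0.621828
9.25,8.88966,0.502891,154.824,30.5812,0.376822,0.449927,17.1621,0.527241
9.75,7.62278,0.430468,133.613,26.2535,0.322782,0.385112,15.2994,0.451027
10.25,6.58333,0.373055,116.151,22.7038,0.279981,0.333584,13.4529,0.390263
10.75,5.72242,0.326977,101.639,19.7642,0.245662,0.292117,11.6778,0.34123
11.25,5.0059,0.288373,89.4813,17.3141,0.216898,0.257418,10.2023,0.30025
11.75,4.40465,0.255774,79.2158,15.2552,0.1926,0.228152,8.96577,0.265725
12.25,3.89633,0.228045,70.485,13.5123,0.171925,0.203285,7.92165,0.236425
12.75,3.46363,0.204302,63.0102,72.0817,0.154215,0.182017,7.03388,0.21139
13.25,3.09296,0.183847,56.5715,64.4679,0.138954,0.163712,6.27423,0.189867
13.75,2.77356,0.166125,50.994,57.8973,0.125726,0.14787,5.62036,0.171257
14.25,2.49685,0.15069,46.1372,52.1964,0.114202,0.134084,5.05447,0.15508
14.75,2.25591,0.137181,41.8872,47.2254,0.104113,0.122031,4.56222,0.140948
15.25,2.04612,0.126136,38.1546,42.8706,0.0958787,0.11212,4.12979,0.129264
15.75,1.86259,0.117082,34.8622,39.039,0.089141,0.103943,3.74838,0.119563
16.25,1.70051,0.108956,31.9438,35.6541,0.0830901,0.0966163,3.41252,0.110886
16.75,1.55682,0.101638,29.3474,32.6523,0.0776374,0.0900292,3.11561,0.103098
17.25,1.42898,0.0950257,27.0294,29.9807,0.0727083,0.0840879,2.85215,0.0960858
17.75,1.31485,0.0890336,24.9531,27.5949,0.068239,0.0787125,2.61758,0.0897517
18.25,1.21264,0.083588,23.0874,25.4575,0.0641753,0.0738353,2.40803,0.0840137
18.75,1.12082,0.0786259,21.4062,23.537,0.0604704,0.0693979,2.22026,0.0788016
19.25,1.03811,0.0740929,19.8869,21.8063,0.0570842,0.0653504,2.05151,0.0740547
19.75,0.963388,0.0699418,18.5104,20.2424,0.0539818,0.0616495,1.89943,0.0697208
20.25,0.897527,0.0666456,17.2594,18.8274,0.051523,0.0586891,1.76397,0.0662296
20.75,0.839284,0.0640776,16.1198,17.5439,0.0496128,0.0563579,1.64294,0.0634526
21.25,0.786076,0.0616752,15.08,16.3754,0.0478246,0.0541808,1.5328,0.0608634
21.75,0.737363,0.0594238,14.1291,15.3092,0.0461479,0.052144,1.43235,0.0584454
22.25,0.692675,0.0573108,13.2579,14.3344,0.0445732,0.0502355,1.34055,0.0561835
22.75,0.651601,0.0553247,12.4579,13.4413,0.0430922,0.0484446,1.25649,0.0540644
23.25,0.613777,0.0534551,69.1209,12.6215,0.0416974,0.0467615,1.17935,0.0520762
23.75,0.578885,0.0516929,65.1267,11.8675,0.0403819,0.0451775,1.10844,0.0502081
24.25,0.546643,0.0500297,61.4395,11.173,0.0391396,0.0436848,1.04314,0.0484506
24.75,0.5168,0.048458,58.0299,10.532,0.0379651,0.0422765,0.982911,0.0467948
25.25,0.489136,0.046971,54.8722,9.93953,0.0368532,0.040946,0.927258,0.0452331
25.75,0.463452,0.0455625,51.9433,9.39105,0.0357995,0.0396875,0.875756,0.0437582
26.25,0.439573,0.0442269,49.2227,8.88253,0.0347997,0.038496,0.828024,0.0423638
26.75,0.41734,0.042959,46.6919,8.41038,0.0338503,0.0373665,0.783723,0.041044
27.25,0.396613,0.0417543,44.3345,7.97138,0.0329476,0.0362947,0.742547,0.0397935
27.75,0.377265,0.0406084,42.1359,7.56267,0.0320885,0.0352767,0.704225,0.0386075
28.25,0.359181,0.0395174,40.0826,7.18166,0.0312703,0.0343088,0.668514,0.0374814
28.75,0.342259,0.0384778,38.1629,6.82603,0.0304902,0.0333878,0.635193,0.0364114
29.25,0.326405,0.0374863,36.3658,6.4937,0.0297458,0.0325104,0.604065,0.0353936
29.75,0.311536,0.0365398,34.6818,6.18277,0.0290349,0.031674,0.574952,0.0344246
30.25,0.298489,0.0358121,33.1012,5.89068,0.0284887,0.0310268,0.548235,0.0336708
30.75,0.287058,0.035285,31.6162,5.61603,0.0280934,0.0305525,0.523682,0.0331128
31.25,0.276239,0.0347752,30.2202,5.3583,0.0277111,0.0300942,0.500599,0.0325742
31.75,0.265991,0.034282,28.9066,5.11622,0.027341,0.0296513,0.478875,0.0320542
32.25,0.256273,0.0338046,27.6692,4.8886,0.0269826,0.0292229,0.458412,0.0315517
32.75,0.247052,0.0333421,26.5027,4.67438,0.0266353,0.0288083,0.439118,0.031066
33.25,0.238296,0.0328939,25.4019,4.47258,0.0262986,0.0284069,0.420911,0.0305962
33.75,0.229973,0.0324594,24.3623,4.28232,0.025972,0.0280181,0.403713,0.0301416
34.25,0.222057,0.0320379,23.3795,4.10277,0.0256551,0.0276412,0.387456,0.0297014
34.75,0.214523,0.0316289,22.4499,3.93319,0.0253474,0.0272758,0.372075,0.029275
35.25,0.207346,0.0312317,21.5696,3.77289,0.0250486,0.0269214,0.357512,0.0288617
35.75,0.200506,0.030846,20.7356,3.62125,0.0247582,0.0265774,0.343711,0.028461
36.25,0.193981,0.0304711,19.9447,3.47769,0.0244759,0.0262434,0.330624,0.0280724
36.75,0.187754,0.0301066,19.1943,3.34166,0.0242014,0.025919,0.318205,0.0276952
37.25,0.181807,0.0297522,18.4816,3.21269,0.0239343,0.0256037,0.306411,0.027329
37.75,0.176124,0.0294074,17.8044,3.09032,0.0236744,0.0252972,0.295202,0.0269734
38.25,0.17069,0.0290718,17.1604,2.97413,0.0234213,0.0249991,0.284543,0.0266278
38.75,0.165491,0.028745,16.5476,2.86373,0.0231748,0.0247092,0.2744,0.0262919
39.25,0.160514,0.0284267,15.9642,2.75877,0.0229346,0.0244269,0.264741,0.0259653
39.75,0.155747,0.0281166,15.4083,2.65891,0.0227005,0.0241522,0.255539,0.0256476
40.25,0.151587,0.027866,14.8795,2.56419,0.0225109,0.0239297,0.247089,0.0253905
40.75,0.147985,0.027672,14.3762,2.47428,0.0223635,0.023757,0.239329,0.025191
41.25,0.144512,0.0274819,13.8958,2.38856,0.0222191,0.0235878,0.231903,0.0249957
41.75,0.14116,0.0272957,13.4368,2.30679,0.0220775,0.0234221,0.224793,0.0248045
42.25,0.137924,0.0271131,12.9983,2.22875,0.0219388,0.0232598,0.217981,0.0246173
42.75,0.134799,0.0269341,12.579,2.15421,0.0218027,0.0231007,0.211453,0.0244339
43.25,0.13178,0.0267586,12.1778,2.083,0.0216691,0.0229447,0.205192,0.0242543
43.75,0.128863,0.0265864,11.7938,2.01491,0.0215381,0.0227918,0.199186,0.0240782
44.25,0.126042,0.0264175,11.4261,1.94979,0.0214096,0.0226418,0.193421,0.0239056
44.75,0.123313,0.0262517,11.0738,1.88747,0.0212834,0.0224947,0.187885,0.0237364
45.25,0.120673,0.0260889,10.7361,1.8278,0.0211595,0.0223504,0.182566,0.0235705
45.75,0.118117,0.0259291,10.4122,1.77064,0.0210378,0.0222087,0.177453,0.0234078
46.25,0.115643,0.0257722,10.1015,1.71586,0.0209183,0.0220697,0.172537,0.0232481
46.75,0.113246,0.0256181,9.80325,1.66334,0.0208009,0.0219332,0.167808,0.0230915
47.25,0.110923,0.0254668,9.51683,1.61296,0.0206856,0.0217992,0.163257,0.0229377
47.75,0.108672,0.025318,9.24166,1.56461,0.0205722,0.0216675,0.158875,0.0227868
48.25,0.10649,0.0251718,8.97719,1.51819,0.0204607,0.0215382,0.154655,0.0226386
48.75,0.104372,0.0250281,8.7229,1.47361,0.0203512,0.0214111,0.150588,0.022493
49.25,0.102318,0.0248869,8.47829,1.43077,0.0202434,0.0212862,0.146669,0.0223501
49.75,0.100325,0.024748,8.24292,1.38959,0.0201375,0.0211635,0.142889,0.0222096
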
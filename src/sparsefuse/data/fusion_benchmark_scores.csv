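method,Data-1|MI,Data-1|EN,Data-1|FMI,Data-1|Qabf,Data-1|VIF,Data-2|MI,Data-2|EN,Data-2|FMI,Data-2|Qabf,Data-2|VIF,Data-3|MI,Data-3|EN,Data-3|FMI,Data-3|Qabf,Data-3|VIF,Data-4|MI,Data-4|EN,Data-4|FMI,Data-4|Qabf,Data-4|VIF,Data-5|MI,Data-5|EN,Data-5|FMI,Data-5|Qabf,Data-5|VIF,Data-6|MI,Data-6|EN,Data-6|FMI,Data-6|Qabf,Data-6|VIF
DWT,2.1141,6.1512,0.7654,0.6656,0.4065,3.5472,5.5481,0.8493,0.6922,0.5593,3.0523,7.1581,0.9438,0.7542,0.5369,3.5962,4.7393,0.3823,0.5835,0.9027,4.0214,4.6386,0.4777,0.5782,0.7592,3.6877,4.8474,0.557,0.4938,0.5551
DTCWT,2.1044,6.2074,0.8341,0.6454,0.3976,3.5201,6.2074,0.8341,0.6756,0.5521,3.0871,7.1287,0.9361,0.7414,0.5348,3.6632,4.8551,0.8339,0.6921,0.6679,4.2985,4.7687,0.4885,0.6257,0.5573,3.6439,4.8839,0.5683,0.5097,0.6086
LP,2.5508,6.2724,0.7412,0.6321,0.4141,3.5908,5.6692,0.8568,0.6571,0.4352,3.1847,7.0536,0.8914,0.7499,0.4832,3.4733,4.6547,0.769,0.6391,0.9255,4.4128,4.8825,0.5241,0.6825,0.5826,3.9482,4.9029,0.6019,0.6287,0.6239
GFF,3.4313,6.7971,0.9032,0.7849,0.4864,3.8595,5.8459,0.8596,0.5919,0.4295,4.0609,5.2463,0.9013,0.6788,0.4486,3.4514,4.4081,0.9047,0.647,0.4961,4.7093,5.2982,0.7849,0.7259,0.7928,4.1675,5.0098,0.7829,0.6876,0.7452
NSCT,2.2087,6.1488,0.7612,0.6872,0.3864,3.511,5.5703,0.8498,0.6837,0.5435,3.7394,7.1873,0.9197,0.7101,0.5132,3.8544,4.536,0.8395,0.7093,0.7769,3.9309,4.9304,0.6908,0.6827,0.7469,3.8888,4.8729,0.7067,0.6431,0.7884
NSST-PAPCNN,2.4665,6.9551,0.4559,0.6968,0.9015,3.5462,7.7278,0.5597,0.5136,0.8393,3.7147,5.3329,0.5536,0.5956,0.8825,3.3372,5.0598,0.5401,0.6076,0.896,4.1937,4.9809,0.736,0.6887,0.6993,4.0671,4.9038,0.7149,0.6835,0.7763
CSR,2.087,6.4871,0.3712,0.6327,0.8041,3.8744,6.0867,0.5614,0.6667,0.4715,3.9478,5.0398,0.8657,0.6342,0.7226,3.6584,4.7695,0.8471,0.6655,0.8467,4.5094,5.0297,0.6997,0.6259,0.5067,3.7432,4.4597,0.6839,0.5334,0.672
CSMCA,2.5863,6.3274,0.4751,0.7373,0.9088,3.5008,7.6182,0.5728,0.5772,0.8615,3.3098,5.0064,0.4679,0.6397,0.9048,3.4007,4.3896,0.4939,0.6601,0.9027,5.0924,5.933,0.7485,0.7759,0.8257,4.581,4.9997,0.8097,0.7482,0.8027
CNN,3.5248,6.7541,0.7712,0.7992,0.8991,4.2014,7.8421,0.7458,0.6969,0.8015,4.0183,6.942,0.9224,0.7301,0.9755,4.254,5.1748,0.8421,0.7441,0.9408,5.1118,5.9989,0.8697,0.8267,0.8881,4.6744,5.2779,0.8527,0.7983,0.8341
Proposed,3.9649,6.9971,0.9781,0.8021,0.9897,4.8821,8.0142,0.885,0.7199,0.8715,4.4388,7.597,0.9744,0.7842,0.9891,4.6987,5.9459,0.9814,0.8023,0.9947,5.2471,6.2874,0.8847,0.8728,0.8971,4.8887,5.8209,0.8817,0.8497,0.8748
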
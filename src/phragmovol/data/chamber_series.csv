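specimen_id,chamber,volume,volume_unit,width_mm
Nm.1,25,0.9,mm3,
Nm.1,26,1.3,mm3,
Nm.1,27,2,mm3,
Nm.1,28,2.1,mm3,2.6
Nm.1,29,2.6,mm3,2.6
Nm.1,30,2.9,mm3,2.7
Nm.1,31,3.4,mm3,2.6
Nm.1,32,4.2,mm3,3.1
Nm.1,33,6,mm3,4.1
Nm.1,34,9.6,mm3,4.1
Nm.1,35,8.6,mm3,4.6
Nm.1,36,10.7,mm3,4.6
Nm.1,37,12.9,mm3,4.6
Nm.1,38,16,mm3,4.6
Nm.1,39,16.2,mm3,4.7
Nm.1,40,26.1,mm3,5.5
Nm.1,41,28.9,mm3,5.8
Nm.1,42,39.2,mm3,6.5
Nm.1,43,49.7,mm3,7.4
Nm.1,44,59.1,mm3,7.9
Nm.1,45,66.7,mm3,8.4
Nm.1,46,81.4,mm3,8.9
Nm.1,47,99.4,mm3,9.4
Nm.1,48,113.3,mm3,9.8
Nm.1,49,155.1,mm3,10.3
Nm.1,50,171.8,mm3,11.3
Nm.1,51,255.9,mm3,12.5
Nm.1,52,338.7,mm3,14.6
Nm.1,53,397.6,mm3,15.1
Nm.1,54,498.5,mm3,16.6
Nm.1,55,557.4,mm3,16.6
Nm.1,56,510.2,mm3,17.5
Nm.1,57,576.1,mm3,17.5
Nm.1,58,528.4,mm3,18
Nm.1,59,497.3,mm3,18
Nm.1,60,410.5,mm3,18
Nm.2,27,1.6,mm3,
Nm.2,28,2.5,mm3,
Nm.2,29,3,mm3,
Nm.2,30,3.8,mm3,
Nm.2,31,4.8,mm3,
Nm.2,32,5.3,mm3,
Nm.2,33,7.4,mm3,
Nm.2,34,8.8,mm3,
Nm.2,35,11.3,mm3,
Nm.2,36,12.4,mm3,
Nm.2,37,16.2,mm3,3.9
Nm.2,38,16.8,mm3,3.9
Nm.2,39,20.4,mm3,4.8
Nm.2,40,30.8,mm3,5.8
Nm.2,41,43.1,mm3,7.2
Nm.2,42,61,mm3,7.7
Nm.2,43,72.4,mm3,7.7
Nm.2,44,78.6,mm3,7.7
Nm.2,45,54,mm3,7.2
Nm.2,46,76.3,mm3,7.2
Nm.2,47,93.1,mm3,7.9
Nm.2,48,130.4,mm3,8.6
Nm.2,49,198.6,mm3,11
Nm.2,50,296,mm3,13.2
Nm.2,51,380.5,mm3,15.1
Nm.2,52,446.4,mm3,15.1
Nm.2,53,458.6,mm3,15.1
Nm.2,54,425.7,mm3,13.9
Nm.2,55,384.6,mm3,13.4
Nm.2,56,409.1,mm3,15.1
Nm.2,57,428.5,mm3,15.4
Nm.2,58,375.1,mm3,15.9
Nm.2,59,339.3,mm3,15.4
7,1,0.0011,ml,
7,2,0.0123,ml,
7,3,0.0468,ml,
7,4,0.1142,ml,
7,5,0.1837,ml,
7,6,0.2236,ml,
7,7,0.1287,ml,
7,8,0.1767,ml,
7,9,0.2265,ml,
7,10,0.2619,ml,
7,11,0.3097,ml,
7,12,0.3254,ml,11.5
7,13,0.3419,ml,12.4
7,14,0.4342,ml,13.2
7,15,0.5986,ml,14.2
7,16,0.6954,ml,15.1
7,17,0.7329,ml,16.3
7,18,0.8595,ml,17
7,19,1.169,ml,17.8
7,20,1.3495,ml,19.1
7,21,1.7666,ml,20.4
7,22,2.0429,ml,21.4
7,23,2.6836,ml,22.9
7,24,3.1432,ml,24.3
7,25,3.8981,ml,26.1
7,26,4.7613,ml,27.4
7,27,6.2645,ml,29.2
7,28,7.6362,ml,31
7,29,8.9947,ml,33.1
7,30,11.6532,ml,36.1
7,31,14.367,ml,38.9
7,32,18.7249,ml,41.7
7,33,22.7825,ml,44.7
7,34,28.9011,ml,47.9
7,35,25.0228,ml,51.5
7,36,,ml,54.5
8,1,0.008,ml,
8,2,0.0331,ml,
8,3,0.1013,ml,
8,4,0.1951,ml,
8,5,0.2417,ml,
8,6,0.1264,ml,
8,7,0.1987,ml,
8,8,0.252,ml,
8,9,0.28,ml,
8,10,0.3126,ml,
8,11,0.4201,ml,13.8
8,12,0.551,ml,14.1
8,13,0.6398,ml,14.5
8,14,0.8348,ml,15.2
8,15,0.9723,ml,16.3
8,16,1.1514,ml,16.6
8,17,1.542,ml,17.4
8,18,1.8436,ml,18.2
8,19,2.4328,ml,19.3
8,20,2.8077,ml,20.4
8,21,3.4284,ml,21.8
8,22,4.7002,ml,22.6
8,23,5.8684,ml,24.6
8,24,7.3975,ml,26.2
8,25,9.2433,ml,30
8,26,12.1851,ml,30.1
8,27,14.8837,ml,32.3
8,28,18.9061,ml,34
8,29,23.4334,ml,36.2
8,30,21.7685,ml,39.7
8,31,,ml,42.4
8,32,,ml,45.2
8,33,,ml,48.3
8,34,,ml,52.8
8,35,,ml,55.6
10,1,0.0082,ml,
10,2,0.0257,ml,
10,3,0.076,ml,
10,4,0.1539,ml,
10,5,0.2028,ml,
10,6,0.1397,ml,
10,7,0.1736,ml,
10,8,0.2027,ml,
10,9,0.2472,ml,
10,10,0.2873,ml,
10,11,0.3461,ml,
10,12,0.4246,ml,
10,13,0.4958,ml,
10,14,0.6386,ml,
10,15,0.7534,ml,
10,16,0.9129,ml,
10,17,0.9722,ml,
10,18,1.263,ml,
10,19,1.6209,ml,
10,20,1.6611,ml,
10,21,2.2127,ml,
10,22,2.4138,ml,
10,23,3.6654,ml,
10,24,3.9932,ml,
10,25,5.955,ml,
10,26,7.2257,ml,
10,27,9.1428,ml,
10,28,11.6261,ml,
10,29,14.3625,ml,
10,30,18.6543,ml,
10,31,22.4427,ml,
10,32,25.6854,ml,
11,1,0.0118,ml,
11,2,0.0416,ml,
11,3,0.1056,ml,
11,4,0.198,ml,
11,5,0.2214,ml,
11,6,0.1244,ml,
11,7,0.2603,ml,
11,8,0.2639,ml,
11,9,0.3593,ml,
11,10,0.4043,ml,
11,11,0.4913,ml,
11,12,0.5882,ml,
11,13,0.6988,ml,
11,14,0.9175,ml,
11,15,1.1123,ml,
11,16,1.2902,ml,
11,17,1.5716,ml,
11,18,2.0393,ml,
11,19,2.3768,ml,
11,20,3.1048,ml,
11,21,3.8014,ml,
11,22,5.1772,ml,
11,23,6.4984,ml,
11,24,6.3292,ml,
11,25,10.878,ml,
11,26,13.0345,ml,
11,27,15.1136,ml,
11,28,15.0097,ml,
11,29,18.0443,ml,
11,30,16.2038,ml,
12,1,0.0139,ml,
12,2,0.0384,ml,
12,3,0.1091,ml,
12,4,0.1809,ml,
12,5,0.205,ml,
12,6,0.1081,ml,
12,7,0.1742,ml,
12,8,0.2046,ml,
12,9,0.237,ml,
12,10,0.3378,ml,
12,11,0.3364,ml,
12,12,0.3992,ml,
12,13,0.4677,ml,
12,14,0.5496,ml,
12,15,0.7096,ml,
12,16,0.8697,ml,
12,17,0.9987,ml,
12,18,1.1376,ml,
12,19,1.4889,ml,
12,20,1.8336,ml,
12,21,2.2195,ml,
12,22,2.8784,ml,
12,23,3.4312,ml,
12,24,4.0784,ml,
12,25,4.8802,ml,
12,26,6.1415,ml,
12,27,7.1537,ml,
12,28,9.3969,ml,
12,29,11.4332,ml,
12,30,13.777,ml,
12,31,17.3911,ml,
12,32,19.8835,ml,
12,33,19.3914,ml,
15,1,0.0088,ml,
15,2,0.0317,ml,
15,3,0.0866,ml,
15,4,0.1571,ml,
15,5,0.2032,ml,
15,6,0.1327,ml,
15,7,0.1711,ml,
15,8,0.1654,ml,
15,9,0.2352,ml,
15,10,0.2344,ml,
15,11,0.2671,ml,
15,12,0.3542,ml,
15,13,0.4407,ml,
15,14,0.5297,ml,
15,15,0.5844,ml,
15,16,0.687,ml,
15,17,0.8377,ml,
15,18,1.0711,ml,
15,19,1.4076,ml,
15,20,1.6886,ml,
15,21,2.2858,ml,
15,22,2.6827,ml,
15,23,3.0022,ml,
15,24,3.9945,ml,
15,25,5.2016,ml,
15,26,6.9912,ml,
15,27,6.9741,ml,
15,28,9.9014,ml,
15,29,13.0762,ml,
15,30,15.9414,ml,
15,31,21.2605,ml,
15,32,25.8978,ml,
15,33,23.7399,ml,
16,1,0.0099,ml,
16,2,0.0145,ml,
16,3,0.0424,ml,
16,4,0.1109,ml,
16,5,0.1859,ml,
16,6,0.2182,ml,
16,7,0.161,ml,
16,8,0.2183,ml,
16,9,0.273,ml,
16,10,0.3047,ml,
16,11,0.3856,ml,
16,12,0.4402,ml,
16,13,0.5293,ml,
16,14,0.6218,ml,
16,15,0.7034,ml,
16,16,0.837,ml,
16,17,1.1188,ml,
16,18,1.3181,ml,
16,19,1.628,ml,
16,20,1.8692,ml,
16,21,2.3806,ml,
16,22,3.0621,ml,
16,23,3.8081,ml,
16,24,4.8836,ml,
16,25,6.4403,ml,
16,26,7.7378,ml,
16,27,10.2469,ml,
16,28,11.9939,ml,
16,29,15.4993,ml,
16,30,18.4287,ml,
16,31,21.4919,ml,
16,32,26.6814,ml,
16,33,21.6118,ml,
17,1,0.0101,ml,
17,2,0.0307,ml,
17,3,0.0882,ml,
17,4,0.1584,ml,
17,5,1.987,ml,
17,6,1.266,ml,
17,7,0.1911,ml,
17,8,0.2065,ml,
17,9,0.2418,ml,
17,10,0.2709,ml,
17,11,0.3332,ml,
17,12,0.4326,ml,
17,13,0.4632,ml,
17,14,0.5654,ml,
17,15,0.7108,ml,
17,16,0.8858,ml,
17,17,1.0799,ml,
17,18,1.3902,ml,
17,19,1.7581,ml,
17,20,2.2017,ml,
17,21,2.7137,ml,
17,22,2.9842,ml,
17,23,4.2956,ml,
17,24,5.7708,ml,
17,25,6.572,ml,
17,26,8.3211,ml,
17,27,9.751,ml,
17,28,12.675,ml,
17,29,15.4005,ml,
17,30,17.8146,ml,
17,31,22.5759,ml,
17,32,25.5356,ml,
17,33,29.6341,ml,
20,1,0.0153,ml,
20,2,0.0329,ml,
20,3,0.0922,ml,
20,4,,ml,
20,5,0.2939,ml,
20,6,0.1387,ml,
20,7,0.1504,ml,
20,8,0.1695,ml,
20,9,0.2092,ml,
20,10,0.2314,ml,
20,11,0.301,ml,
20,12,0.4017,ml,
20,13,0.3846,ml,
20,14,0.5069,ml,
20,15,0.5902,ml,
20,16,0.7431,ml,
20,17,0.9711,ml,
20,18,1.174,ml,
20,19,1.5174,ml,
20,20,1.8071,ml,
20,21,2.2284,ml,
20,22,2.8115,ml,
20,23,3.374,ml,
20,24,4.302,ml,
20,25,5.5132,ml,
20,26,6.5154,ml,
23,1,0.012,ml,
23,2,0.037,ml,
23,3,0.144,ml,
23,4,0.1904,ml,
23,5,0.1658,ml,
23,6,,ml,
23,7,0.1875,ml,
23,8,0.2451,ml,
23,9,0.3563,ml,
23,10,0.3615,ml,
23,11,0.2962,ml,
23,12,0.5029,ml,
23,13,0.6454,ml,
23,14,0.7712,ml,
23,15,0.8968,ml,
23,16,1.0808,ml,
23,17,1.3026,ml,
23,18,1.5484,ml,
23,19,1.78,ml,
23,20,2.4023,ml,
23,21,2.86,ml,
23,22,3.4343,ml,
23,23,4.4262,ml,
23,24,5.5624,ml,
23,25,6.8422,ml,
23,26,8.3682,ml,
53,11,,ml,13.8
53,12,,ml,14.1
53,13,,ml,14.5
53,14,,ml,15.2
53,15,,ml,16.3
53,16,,ml,16.6
53,17,,ml,17.4
53,18,,ml,18.2
53,19,,ml,19.3
53,20,,ml,20.4
53,21,,ml,21.8
53,22,,ml,22.6
53,23,,ml,24.6
53,24,,ml,26.2
53,25,,ml,30
53,26,,ml,30.1
53,27,,ml,32.3
53,28,,ml,34
53,29,,ml,36.2
53,30,,ml,39.7
53,31,,ml,42.4
53,32,,ml,45.2
53,33,,ml,48.3
53,34,,ml,52.8
53,35,,ml,55.6
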
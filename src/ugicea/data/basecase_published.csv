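age_band,strategy,qalys,inc_qalys_vs_none,inc_qalys_vs_next,cost_thousand,inc_cost_vs_none_thousand,inc_cost_vs_next_thousand,icer_vs_none,icer_vs_next
40-44,no_screening,1659260,,,25035,,,,
40-44,once_per_lifetime,1660347,1087,1087,28334,3299,3299,3035,3035
40-44,every_10y,1663677,4417,3330,31954,6919,3620,1566,1087
40-44,every_5y,1666345,7085,2668,36707,11672,4753,1647,1781
40-44,every_3y,1668371,9111,2026,42218,17183,5511,1886,2720
40-44,every_2y,1669622,10362,1251,47861,22826,5643,2203,4511
45-49,no_screening,1572532,,,26817,,,,
45-49,once_per_lifetime,1574161,1629,1629,30347,3530,3530,2167,2167
45-49,every_10y,1576941,4409,2780,33961,7144,3614,1620,1300
45-49,every_5y,1579145,6613,2204,37745,10928,3784,1653,1717
45-49,every_3y,1580974,8442,1829,42531,15714,4786,1861,2617
45-49,every_2y,1582334,9802,1360,48190,21373,5659,2180,4161
50-54,no_screening,1468506,,,30229,,,,
50-54,once_per_lifetime,1470890,2384,2384,34142,3913,3913,1641,1641
50-54,every_10y,1472583,4077,1693,36373,6144,2231,1507,1318
50-54,every_5y,1474773,6267,2190,40356,10127,3983,1616,1819
50-54,every_3y,1476325,7819,1552,44120,13891,3764,1777,2425
50-54,every_2y,1477651,9145,1326,49010,18781,4890,2054,3688
55-59,no_screening,1342830,,,36095,,,,
55-59,once_per_lifetime,1346031,3201,3201,40491,4396,4396,1373,1373
55-59,every_10y,1347264,4434,1233,42811,6716,2320,1515,1882
55-59,every_5y,1348747,5917,1483,45240,9145,2429,1546,1638
55-59,every_3y,1350365,7535,1618,49171,13076,3931,1735,2430
55-59,every_2y,1351491,8661,1126,52843,16748,3672,1934,3261
60-64,no_screening,1195742,,,45876,,,,
60-64,once_per_lifetime,1199618,3876,3876,51081,5205,5205,1343,1343
60-64,every_5y,1201091,5349,1473,53970,8094,2889,1513,1961
60-64,every_3y,1202293,6551,1202,56498,10622,2528,1621,2103
60-64,every_2y,1203210,7468,917,58779,12903,2281,1728,2487
65-69,no_screening,1025119,,,60442,,,,
65-69,once_per_lifetime,1029058,3939,3939,67233,6791,6791,1724,1724
65-69,every_2y,1030594,5475,1536,70810,10368,3577,1894,2329
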
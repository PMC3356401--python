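index,rs_id,gene,label1,label2,label3,case1,case2,case3,control1,control2,control3
1,rs6269,COMT,AA,AG,GG,1694,2389,917,1769,2390,841
2,rs4680,COMT,GG,GA,AA,1308,2440,1252,1377,2417,1206
3,rs10046,CYP19A1,CC,CT,TT,1434,2411,1155,1430,2497,1073
4,rs3020314,ESR1,CC,CT,TT,2147,2280,573,2343,2164,493
5,rs2234693,ESR1,TT,TC,CC,1446,2480,1074,1450,2524,1026
6,rs1543404,ESR1,TT,TC,CC,1468,2439,1093,1467,2441,1092
7,rs3798577,ESR1,TT,TC,CC,1413,2494,1093,1406,2542,1052
8,rs2747652,ESR1,CC,CT,TT,1377,2479,1144,1372,2447,1181
9,rs2077647,ESR1,AA,AG,GG,1383,2449,1168,1347,2589,1064
10,rs2175898,ESR1,AA,AG,GG,1350,2507,1143,1353,2457,1190
11,rs9340799,ESR1,AA,AG,GG,2016,2360,624,2107,2302,591
12,rs1709182,ESR1,TT,TC,CC,1932,2326,742,1988,2341,671
13,rs9478249,ESR1,TT,TG,GG,1890,2381,729,1773,2430,797
14,rs1514348,ESR1,CC,CA,AA,1717,2435,851,1830,2415,755
15,rs532010,ESR1,TT,TC,CC,1848,2377,775,1891,2422,687
16,rs566351,PGR,TT,TC,CC,2062,2280,658,2014,2326,660
17,rs660149,PGR,CC,CG,GG,2708,1927,365,2591,2042,367
18,rs11571171,PGR,TT,TC,CC,2419,2082,499,2338,2163,499
19,rs500760,PGR,AA,AG,GG,2888,1866,246,2994,1767,239
20,rs858518,SHBG,TT,TC,CC,1693,2412,895,1597,2490,913
21,rs272428,SHBG,CC,CT,TT,1609,2438,953,1523,2442,1035
22,rs858524,SHBG,AA,AG,GG,1613,2459,928,1725,2393,882
23,rs2017591,STS,TT,TC,CC,1823,2258,919,1760,2437,803
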
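seed	mirna_id	n_conserved	percent_printed	n_total
CGUUUGC	hsa-mir-1282	1	0.0025	398
CGUGUCU	hsa-mir-187	3	0.0068	439
CCGGUUC	hsa-mir-671-3p	5	0.0175	285
AACCGUU	hsa-mir-451	14	0.0433	323
CGUACCG	hsa-mir-126	17	0.1328	128
GGACGGA	hsa-mir-184	21	0.0363	578
AACGGAA	hsa-mir-191	32	0.0691	463
CUCUAGC	hsa-mir-1251	57	0.0348	1636
AUACCUC	hsa-mir-875-5p	64	0.0530	1207
GAGUUGA	hsa-mir-219-1-3p	65	0.0426	1525
CAUGGAU	hsa-mir-490-5p	75	0.0402	1866
GGGUCUU	hsa-mir-193a-5p	78	0.0404	1933
GAAUUGU	hsa-mir-219-2-3p	93	0.0546	1704
GAUCAGA	hsa-mir-383	101	0.0645	1565
AACCUGG	hsa-mir-490-3p	102	0.0519	1964
AUCACUA	hsa-mir-34c-3p	111	0.0645	1720
AUGACAC	hsa-mir-425	112	0.0566	1978
GGAGUGU	hsa-mir-122	116	0.0463	2503
AUGUGCC	hsa-mir-455-5p	128	0.0790	1620
UUGUUCG	hsa-mir-375	136	0.0756	1799
UUGUGUC	hsa-mir-599	138	0.0588	2347
UGACAUC	hsa-mir-489	138	0.0668	2067
AGUAGUU	hsa-mir-1244	140	0.0987	1419
CAUAUUG	hsa-mir-1279	146	0.0636	2296
AAUCUCA	hsa-mir-216a	153	0.0681	2248
CAGGAAC	hsa-mir-873	167	0.0524	3184
AAUGCCC	hsa-mir-365	171	0.1050	1628
AAUCUCU	hsa-mir-216b	172	0.0814	2113
CAGUCCA	hsa-mir-455-3p	181	0.0816	2217
CCAGCAU	hsa-mir-338-3p	189	0.0691	2736
GUCAGUU	hsa-mir-223	193	0.1051	1837
GGAAGCC	hsa-mir-671-5p	201	0.0806	2493
AAUCACU	hsa-mir-34b	217	0.0939	2312
ACUGCAU	hsa-mir-217	223	0.0985	2265
ACCACAG	hsa-mir-140-3p	223	0.0843	2644
GGCAAGA	hsa-mir-31	227	0.0985	2305
AGUGGUU	hsa-mir-140-5p	237	0.1424	1664
GUAGUGU	hsa-mir-142-3p	241	0.1971	1223
GAGGUAG	hsa-mir-98	243	0.1753	1386
GUAACAG	hsa-mir-194	246	0.1118	2200
UAAUGCU	hsa-mir-155	268	0.1419	1888
AUGGCAC	hsa-mir-183	283	0.1429	1980
CCUUCAU	hsa-mir-205	284	0.1115	2548
GGAAGAC	hsa-mir-7	286	0.1004	2848
AGCUGCC	hsa-mir-22	308	0.1381	2231
UUUUUGC	hsa-mir-129-5p	334	0.0827	4040
GCUGGUG	hsa-mir-138	368	0.1531	2403
CUGGAAA	hsa-mir-875-3p	412	0.1135	3629
GGCUCAG	hsa-mir-24	417	0.1206	3458
AAAGAAU	hsa-mir-186	498	0.1149	4333
UCCAGUU	hsa-mir-145	504	0.1980	2545
UGCAUAG	hsa-mir-153	515	0.2702	1906
AUAAAGU	hsa-mir-142-5p	516	0.1655	3117
GAGGUAU	hsa-mir-202	569	0.3506	1623
ACAGUAC	hsa-mir-101	582	0.2358	2468
ACAAUAU	hsa-mir-338-5p	587	0.1952	3007
ACAGUAU	hsa-mir-144	616	0.2290	2690
UGUGCUU	hsa-mir-218	665	0.2847	2336
UAUUGCU	hsa-mir-137	817	0.3719	2197
CUUUGGU	hsa-mir-9	893	0.3323	2687
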
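#exon	cdna_start	cdna_end
1	1	97
2	98	151
3	152	225
4	226	368
5	369	445
6	446	513
7	514	593
8	594	898
9	899	1010
10	1011	1151
11	1152	1292
12	1293	1307
13	1308	1381
14	1382	1528
15	1529	1555
16	1556	1582
17	1583	1638
18	1639	1708
19	1709	1724
20	1725	1857
21	1858	1962
22	1963	2010
23	2011	2193
24	2194	2206
25	2207	2280
26	2281	2381
27	2382	2588
28	2589	2677
29	2678	2735
30	2736	2866
31	2867	2895
32	2896	2974
33	2975	3507
34	3508	3548
35	3549	3652
36	3653	3742
37	3743	3895
38	3896	3968
39	3969	3989
40	3990	4023
41	4024	4165
42	4166	4325
43	4326	4528
44	4529	4576
45	4577	4705
46	4706	4994
47	4995	5025
48	5026	5042
49	5043	5080
50	5081	5243
51	5244	5259
52	5260	5366
53	5367	5382
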
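#exon	cdna_start	cdna_end
1	1	89
2	90	174
3	175	483
4	484	666
5	667	751
6	752	965
7	966	1001
8	1002	1194
9	1195	1291
10	1292	1428
11	1429	1561
12	1562	1645
13	1646	1774
14	1775	1815
15	1816	1911
16	1912	2004
17	2005	2150
18	2151	2223
19	2224	2286
20	2287	2364
21	2365	2407
22	2408	2720
23	2721	2830
24	2831	2875
25	2876	3117
26	3118	3228
27	3229	3262
28	3263	3297
29	3298	3418
30	3419	3541
31	3542	3581
32	3582	3657
33	3658	3746
34	3747	3768
35	3769	3939
36	3940	4015
37	4016	4286
38	4287	4341
39	4342	4493
40	4494	4546
41	4547	4580
42	4581	4615
43	4616	4675
44	4676	4756
45	4757	4794
46	4795	4918
47	4919	5125
48	5126	5142
49	5143	5183
50	5184	5268
51	5269	5492
52	5493	5658
53	5659	5748
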
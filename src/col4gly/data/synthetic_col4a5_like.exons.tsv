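#exon	cdna_start	cdna_end
1	1	39
2	40	140
3	141	185
4	186	346
5	347	408
6	409	576
7	577	777
8	778	878
9	879	957
10	958	1127
11	1128	1300
12	1301	1393
13	1394	1431
14	1432	1664
15	1665	1687
16	1688	1924
17	1925	1989
18	1990	2026
19	2027	2113
20	2114	2244
21	2245	2263
22	2264	2420
23	2421	2468
24	2469	2498
25	2499	2630
26	2631	2697
27	2698	2962
28	2963	3003
29	3004	3087
30	3088	3165
31	3166	3274
32	3275	3397
33	3398	3416
34	3417	3550
35	3551	3624
36	3625	3665
37	3666	3734
38	3735	3997
39	3998	4071
40	4072	4131
41	4132	4149
42	4150	4177
43	4178	4308
44	4309	4456
45	4457	4474
46	4475	4508
47	4509	4712
48	4713	4790
49	4791	4816
50	4817	4839
51	4840	4985
52	4986	5147
53	5148	5394
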
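# SYNTHETIC chain architecture: randomly generated stand-in calibrated to
# published collagen IV geometry (23 local collagenous regions, boundary
# Gly ~1/10 of collagenous Gly). Not the real reference chain.
#kind	start	end
amino_terminus	1	27
collagenous	28	78
interruption	79	89
collagenous	90	164
interruption	165	173
collagenous	174	236
interruption	237	240
collagenous	241	309
interruption	310	318
collagenous	319	372
interruption	373	378
collagenous	379	429
interruption	430	440
collagenous	441	482
interruption	483	494
collagenous	495	542
interruption	543	547
collagenous	548	616
interruption	617	623
collagenous	624	683
interruption	684	687
collagenous	688	747
interruption	748	756
collagenous	757	822
interruption	823	831
collagenous	832	894
interruption	895	905
collagenous	906	962
interruption	963	972
collagenous	973	1035
interruption	1036	1047
collagenous	1048	1122
interruption	1123	1134
collagenous	1135	1194
interruption	1195	1205
collagenous	1206	1250
interruption	1251	1253
collagenous	1254	1319
interruption	1320	1321
collagenous	1322	1369
interruption	1370	1376
collagenous	1377	1424
interruption	1425	1429
collagenous	1430	1507
interruption	1508	1518
collagenous	1519	1569
carboxyl_terminus	1570	1798
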
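# SYNTHETIC chain architecture: randomly generated stand-in calibrated to
# published collagen IV geometry (23 local collagenous regions, boundary
# Gly ~1/10 of collagenous Gly). Not the real reference chain.
#kind	start	end
amino_terminus	1	27
collagenous	28	69
interruption	70	74
collagenous	75	137
interruption	138	139
collagenous	140	175
interruption	176	185
collagenous	186	272
interruption	273	275
collagenous	276	329
interruption	330	336
collagenous	337	402
interruption	403	404
collagenous	405	470
interruption	471	472
collagenous	473	544
interruption	545	555
collagenous	556	618
interruption	619	620
collagenous	621	674
interruption	675	681
collagenous	682	729
interruption	730	735
collagenous	736	810
interruption	811	813
collagenous	814	873
interruption	874	882
collagenous	883	939
interruption	940	949
collagenous	950	1015
interruption	1016	1027
collagenous	1028	1105
interruption	1106	1109
collagenous	1110	1163
interruption	1164	1175
collagenous	1176	1256
interruption	1257	1258
collagenous	1259	1312
interruption	1313	1315
collagenous	1316	1372
interruption	1373	1380
collagenous	1381	1413
interruption	1414	1424
collagenous	1425	1499
interruption	1500	1510
collagenous	1511	1561
carboxyl_terminus	1562	1794
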
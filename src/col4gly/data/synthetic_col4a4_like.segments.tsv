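# SYNTHETIC chain architecture: randomly generated stand-in calibrated to
# published collagen IV geometry (23 local collagenous regions, boundary
# Gly ~1/10 of collagenous Gly). Not the real reference chain.
#kind	start	end
amino_terminus	1	38
collagenous	39	110
interruption	111	115
collagenous	116	184
interruption	185	192
collagenous	193	249
interruption	250	258
collagenous	259	348
interruption	349	353
collagenous	354	401
interruption	402	404
collagenous	405	479
interruption	480	491
collagenous	492	539
interruption	540	543
collagenous	544	633
interruption	634	635
collagenous	636	692
interruption	693	698
collagenous	699	755
interruption	756	757
collagenous	758	808
interruption	809	817
collagenous	818	886
interruption	887	889
collagenous	890	946
interruption	947	951
collagenous	952	1023
interruption	1024	1028
collagenous	1029	1097
interruption	1098	1106
collagenous	1107	1169
interruption	1170	1180
collagenous	1181	1228
interruption	1229	1237
collagenous	1238	1303
interruption	1304	1311
collagenous	1312	1392
interruption	1393	1396
collagenous	1397	1459
interruption	1460	1468
collagenous	1469	1540
interruption	1541	1550
collagenous	1551	1616
interruption	1617	1618
collagenous	1619	1687
carboxyl_terminus	1688	1916
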
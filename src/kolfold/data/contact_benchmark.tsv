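protein	method	tp	fp	fn	tn	mcc
2auha	VRN	122	1294	714	40648	0.0890
2auha	KLM	269	1264	506	40739	0.2275
2b4sb	VRN	124	1283	724	40647	0.0904
2b4sb	KLM	270	1253	516	40739	0.2273
1ybia	VRN	90	1274	81	38741	0.1778
1ybia	KLM	361	1301	844	37680	0.2280
1ybib	VRN	88	1273	80	38745	0.1755
1ybib	KLM	362	1299	845	37680	0.2286
1n8ka	VRN	482	1880	5631	61758	0.0771
1n8ka	KLM	589	1880	5622	61660	0.1006
1ye3	VRN	494	1905	5607	61745	0.0791
1ye3	KLM	601	1905	5598	61647	0.1024
1ulka	VRN	54	573	273	6975	0.0658
1ulka	KLM	91	586	261	6937	0.1332
1ulkb	VRN	58	562	262	6993	0.0783
1ulkb	KLM	91	574	249	6961	0.1400
1kx5a	VRN	276	343	1904	6522	0.1298
1kx5a	KLM	96	360	343	8246	0.1737
1kx5e	VRN	274	348	1898	6525	0.1275
1kx5e	KLM	95	365	337	8248	0.1723
1tpda	VRN	529	1086	5953	23308	0.0678
1tpda	KLM	379	1043	2526	26928	0.1298
5tim_	VRN	543	1111	5928	23294	0.0694
5tim_	KLM	390	1068	2501	26917	0.1329
1ftja	VRN	293	1094	1854	29912	0.1244
1ftja	KLM	262	1102	1043	30746	0.1627
1fw0a	VRN	290	1084	1864	29915	0.1232
1fw0a	KLM	267	1092	1053	30741	0.1656
1ewka	VRN	312	2110	3348	94806	0.0775
1ewka	KLM	523	2110	5270	92673	0.0993
1ewkb	VRN	306	2081	3377	94812	0.0760
1ewkb	KLM	528	2081	5299	92668	0.1009
1bpxa	VRN	335	1337	4282	47021	0.0725
1bpxa	KLM	159	1395	1020	50401	0.0943
1bpya	VRN	333	1329	4291	47022	0.0721
1bpya	KLM	159	1386	1028	50402	0.0943
1aonn	VRN	97	2534	627	133768	0.0610
1aonn	KLM	390	2491	1250	132895	0.1663
1xck	VRN	94	2570	663	133699	0.0565
1xck	KLM	392	2526	1214	132894	0.1681
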
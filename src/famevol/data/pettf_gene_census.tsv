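# Published per-gene statistics for the 35 Moso bamboo trihelix (PeTTF) family members.
# Columns: gene, locus, chrom, start, end (1-based inclusive genomic span), orf_bp, aa_len, mw_da, pi, exons
gene	locus	chrom	start	end	orf_bp	aa_len	mw_da	pi	exons
PeTTF1	PH01000001G0500	PH01000001	348404	353246	1392	463	51339.99	6.51	6
PeTTF2	PH01000010G0450	PH01000010	333451	334674	837	278	31526.86	10.51	2
PeTTF3	PH01000016G1050	PH01000016	832203	835604	978	325	35416.69	6.71	4
PeTTF4	PH01000017G1770	PH01000017	1223108	1227861	1632	543	57598.78	6.66	4
PeTTF5	PH01000019G0430	PH01000019	338352	344501	1776	591	64500.43	8.28	7
PeTTF6	PH01000019G0630	PH01000019	498070	502996	1251	416	44129.17	6.53	6
PeTTF7	PH01000020G1490	PH01000020	1016528	1021991	1161	386	42551.58	6.42	5
PeTTF8	PH01000023G2170	PH01000023	1389503	1390380	591	196	21556.89	10.89	1
PeTTF9	PH01000042G1290	PH01000042	820202	822366	1632	543	59326.99	5.33	1
PeTTF10	PH01000110G0890	PH01000110	616131	618576	522	173	18904.82	10.00	1
PeTTF11	PH01000225G1300	PH01000225	784587	789545	813	270	31899.86	8.69	2
PeTTF12	PH01000265G1050	PH01000265	729361	733771	1266	421	45424.90	9.18	8
PeTTF13	PH01000551G0750	PH01000551	454513	457660	1317	438	49565.35	6.18	1
PeTTF14	PH01000749G0800	PH01000749	497748	502389	816	271	29897.93	9.04	6
PeTTF15	PH01000778G0550	PH01000778	319370	322783	942	313	34196.71	9.96	1
PeTTF16	PH01000823G0680	PH01000823	401827	404100	1140	379	43468.32	9.03	1
PeTTF17	PH01000907G0490	PH01000907	299223	301005	690	229	6250.04	9.30	2
PeTTF18	PH01001050G0190	PH01001050	145304	146705	609	202	22559.24	9.84	2
PeTTF19	PH01001160G0450	PH01001160	304848	307615	732	243	27274.24	6.72	3
PeTTF20	PH01001191G0080	PH01001191	45575	48488	1026	341	34296.75	6.88	1
PeTTF21	PH01001215G0530	PH01001215	388790	394765	1695	564	62006.92	9.62	6
PeTTF22	PH01001227G0510	PH01001227	318856	320192	981	326	35750.42	6.81	1
PeTTF23	PH01001447G0230	PH01001447	145073	149866	1059	352	37733.79	5.19	3
PeTTF24	PH01001451G0080	PH01001451	28239	32258	1935	644	70109.82	5.76	3
PeTTF25	PH01001538G0330	PH01001538	231626	234572	1047	348	38256.31	6.22	3
PeTTF26	PH01001567G0130	PH01001567	89093	92345	756	251	27067.65	9.81	1
PeTTF27	PH01001778G0330	PH01001778	262830	265479	1287	428	48983.77	6.27	1
PeTTF28	PH01002213G0310	PH01002213	194429	199841	1485	494	54202.70	8.38	7
PeTTF29	PH01002648G0060	PH01002648	37644	39402	1200	399	46125.49	6.13	1
PeTTF30	PH01003510G0200	PH01003510	123649	126664	1329	442	50199.08	6.35	1
PeTTF31	PH01008287G0010	PH01008287	1698	5966	1926	641	70113.15	5.60	3
PeTTF32	PH01011203G0010	PH01011203	229	1679	600	199	22030.79	6.53	3
PeTTF33	PH01047850G0010	PH01047850	55	1624	897	298	31134.39	4.85	3
PeTTF34	PH01107020G0010	PH01107020	53	1034	624	207	21063.61	9.94	3
PeTTF35	PH01153193G0010	PH01153193	1	820	477	158	17923.39	4.68	2
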
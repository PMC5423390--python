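# Control-condition transcripts with cross-laboratory CV > 3 SD above the mean (GSE47752 consortium reference list)
gene_symbol	group_median	cv_pct
LOC100909504	2944	82.9
Mis18a	238	61.9
Ttr	557	60.0
Prkcb	109	58.0
Coch	59.8	56.9
Ptgds	415	52.6
Slc17a6	195	51.9
Fam111a	59.6	50.6
Atp1a3	1821	50.3
Dnajb6	1310	50.0
LOC257642	1229	49.2
Caly	2598	48.3
Htr2c	179	47.9
Hba1///Hba2	1331	46.6
Cartpt	649	46.5
LOC102546420	44.5	46.2
Got1	842	45.7
Adam22	1267	45.7
Aplp1	1636	43.9
Tbl1xr1	89.1	43.7
Smarca2	249	43.7
Ctxn1	2175	43.5
Enc1	2074	43.0
Psmd14	582	42.7
LOC100911806	128	42.6
Myo5b	538	42.6
Cdh13	779	42.0
LOC100911286///Pcsk1n	3750	41.5
Slitrk3	614	41.4
Atxn2	280	41.0
Arhgap12	164	40.9
Wasl	816	40.6
Slc35g2	112	40.3
Sostdc1	60.4	40.2
Prpf40a	107	40.1
Colec12	47.0	39.8
Cacnb3	384	39.6
Pfkl	186	39.6
Tsc22d2	446	39.4
Pianp	301	39.2
Gria1	3116	38.9
Arl8b	229	38.5
Ccnd2	1095	38.5
Atp6v0a1	790	38.5
LOC100364062///Pkm	5747	38.5
Brinp1	1396	38.4
Nsg2	3176	38.2
Enpp2	375	37.8
Slc17a7	1062	37.7
Tanc2	144	37.7
Slitrk1	817	37.6
LOC679818	160	37.3
Pkib	596	37.0
F5	38.5	36.9
Rad17	227	36.8
Map1b	327	36.7
Mlf2	3229	36.4
Cox5a	318	36.3
Cth	150	36.3
Lsamp	717	36.2
Ppp1r1b	950	36.2
Hpcal4	596	36.2
Myt1l	1582	36.2
Cnih2	4609	35.9
Tspyl2	684	35.8
Atp5a1	4092	35.8
Nmrk1	264	35.6
Sh3bgrl	343	35.6
Tecpr1	428	35.6
Sorl1	877	35.5
Prps1	783	35.5
Atg12	191	35.5
Glyr1	1255	35.4
RGD1564664	216	35.3
Mthfd1l	139	35.3
Pfn2	196	35.3
Dnajc5	415	35.2
Chsy3///LOC100910780	96.1	35.2
Slc12a5	9635	35.1
Faim2	881	35.1
Cacna2d1	833	35.1
Atp6v0c	6859	35.0
Nucb1	784	35.0
RGD1565798///Tpt1	8075	34.8
Rcan1	161	34.8
Cck	576	34.8
Apod	210	34.8
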
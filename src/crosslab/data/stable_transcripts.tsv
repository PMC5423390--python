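# Control-condition transcripts with cross-laboratory CV < 3% (GSE47752 consortium reference list)
gene_symbol	group_median	cv_pct
Dock6	108	1.16
Ankrd13b	131	1.35
Lrba	109	1.40
Zcchc8	87	1.74
Cad	106	1.77
Zfp758	45	1.81
Timm8a1	151	1.87
Ints9 /// LOC102549712	577	1.93
Pikfyve	310	2.01
Golph3l	138	2.03
Rps6kb1	1684	2.07
Zzef1	121	2.10
Khnyn	74	2.12
Lrfn1	462	2.15
Cryz	109	2.16
Fkbp15	126	2.19
Setd1b	107	2.19
Pacs1	152	2.24
Mlxip	214	2.27
Mtmr10	115	2.29
Strn	186	2.32
Ddx26b	1001	2.33
Lrrc61	167	2.43
Chm	46	2.45
Stx3	106	2.47
Synm	151	2.49
Ddx52	123	2.49
Ripk1	73	2.49
LOC102549467	19	2.51
Nr2c1	44	2.60
Spin4	33	2.61
Isoc2b	92	2.63
Klf2	106	2.64
Ubfd1	133	2.66
Nol10	1068	2.67
RGD1562608	109	2.67
Creb3l2	38	2.68
Gpr137	216	2.70
Blm	212	2.74
RGD1305422	162	2.75
Arfgef1	381	2.76
LOC102546678///Prrg3	120	2.78
Bnip1	113	2.81
LOC102552625	212	2.82
LOC100911725///Pfkfb4	69	2.83
Man1b1	229	2.86
Lepre1	111	2.88
Optc	22	2.89
LOC100912473	70	2.89
Gmds	485	2.89
Adssl1	34	2.89
Scp2d1	28	2.93
Sult2b1	97	2.94
Zbtb12	34	2.95
Casp9	105	2.95
Palm3	116	2.98
Sap30bp	224	2.98
Zfp367	32	2.99
Med27	2190	2.99
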
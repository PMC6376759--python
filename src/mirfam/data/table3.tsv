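cluster	mir_ids	unique_seq	uts_id	uts_seq	evalue	upe	accession	description	inhibition
1	ath-miR394a;ath-miR394b-5p;osa-miR394;sbi-miR394a;sbi-miR394b;zma-miR394a-5p;zma-miR394b-5p;ptc-miR394a-5p;ptc-miR394b-5p;vvi-miR394b;ghr-miR394a;ghr-miR394b;aly-miR394a-5p;aly-miR394b-5p;ahy-miR394;gma-miR394b-5p;gma-miR394a-5p;gma-miR394c-5p;gma-miR394d;gma-miR394e;gma-miR394f;gma-miR394g;csi-miR394;tcc-miR394a;tcc-miR394b;bdi-miR394;ssl-miR394;bna-miR394a;bna-miR394b;mes-miR394a;mes-miR394b;cca-miR394;lus-miR394a;lus-miR394b;nta-miR394;ppe-miR394a;ppe-miR394b;mdm-miR394a;mdm-miR394b;cme-miR394a;cme-miR394b;cpa-miR394a;cpa-miR394b;atr-miR394;sly-miR394-5p;ata-miR394-5p;ini-miR394;csa-miR394a;csa-miR394b;csa-miR394c;nnu-miR394;jre-miR394;mac-miR394;era-miR394;nto-miR394;rsa-miR394a;rsa-miR394b;rsa-miR394c;aip-miR394;adu-miR394;egu-miR394;cst-miR394a;cst-miR394b;fve-miR394;peu-miR394a;peu-miR394b	UUGGCAUUCUGUCCACCUCC	1a	GGAGGUUGACAGAAUGCCAA	1	14.87	AT1G27340	Ath-LCR LEAF CURLING RESPONSIVENESS	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	16.78	POPTR_0001s13770g	Ptc-F-box family protein	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	17.38	POPTR_0003s16980g	Ptc-hypo (F-box)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	16.82	LOC100242085	Vvi-F-box family protein	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	15.82	LOC100800464	Gma-F-box only protein 6-like (1)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	13.67	LOC100810179	Gma-F-box only protein 6-like (2)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	15.65	LOC100795488	Gma-F-box only protein 6-like (3)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	16.47	LOC109152509	Ini-F-box only protein 6-like (1)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	14.044	LOC109175636	Ini-F-box only protein 6-like (2)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	14.867	LOC104757055	Csa-F-box only protein 6-like (1)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	15.009	LOC104741342	Csa-F-box only protein 6-like (2)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	14.867	LOC104776781	Csa-F-box only protein 6-like (3)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	17.161	LOC104592877	Nnu-F-box only protein 6-like (1)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	16.572	LOC104591738	Nnu-F-box only protein 6-like (2)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	15.37	LOC109003194	Jre-F-box only protein 6-like (1)	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	16.4	LOC104415679	Era-F-box only protein 6	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	17.6	LOC104116922	Nto-F-box only protein 6	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	17.61	LOC108809705	Rsa-F-box only protein 6	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	17.1	LOC101211089	Cst-F-box only protein 6	Cleavage
1			1a	GGAGGUUGACAGAAUGCCAA	1	15.55	LOC101312115	Fve-F-box only protein 6	Cleavage
1			1b	GGAUGUGUGCAGAGUGCCAA	3	15.92	AT3G48460	Ath-GDSL-motif esterase/acyltransferase/lipase	Cleavage
1			1c	GGAGGAGGACAGAGAUGCCAA	3	24.57	AT5G09670	Ath-loricrin-related	Cleavage
1			1d	GGAGGUGGAAGAAUGCCGG	3	20.99	AT3G12120	Ath-ATFAD2 FATTY ACID DESATURASE 2	Translation
1			1e	GGAGGUGGACAGAAUGCCAA	0	21.42	Os01g69940	Osa-OsFBX32 F-box domain containing protein	Cleavage
1			1e	GGAGGUGGACAGAAUGCCAA	0	23.55	SORBIDRAFT_03g044270	Sbi-hypo 1 (F-box domain)	Cleavage
1			1e	GGAGGUGGACAGAAUGCCAA	0	23.11	LOC103636344	Zma-F-box only protein 6-like (not annotated)	Cleavage
1			1e	GGAGGUGGACAGAAUGCCAA	0	22.96	LOC100193727	Zma-Uncharacterized1 (F-box only protein 6-like)	Cleavage
1			1e	GGAGGUGGACAGAAUGCCAA	0	22.083	LOC103972833	Mac-F-box only protein 6	Cleavage
1			1f	GGAGGUCGACAGAAUGCCAA	1	14.89	LOC105962383	Egu-F-box only protein 6	Cleavage
1			1g	GGAGUUGGACAGAAUGCAAA	2.5	13.3	Os05g51150	Osa-RNA polymerase sigma factor	Cleavage
1			1h	CAAGGUGGACAGAAUGCUAA	2.5	16.14	SORBIDRAFT_02g034550	Sbi-hypo 2 (Transcription factor GRAS)	Cleavage
1			1i	GGAAGUGGACAGAGUGCUGA	2.5	18.13	LOC100242751	Vvi-PMT18	Cleavage
1			1j	GAAGGUGGACAGAGUGCUAC	3	20.26	LOC100253052	Vvi-FGGY carbohydrate kinase domain-containing protein	Cleavage
1			1k	GGAGGUAGACAGAAUGCCAA	1	18.77	LOC109010064	Jre-F-box only protein 6-like (2)	Cleavage
1			1k	GGAGGUAGACAGAAUGCCAA	1	14.65	LOC107631986	Aip-F-box only protein 6	Cleavage
1			1k	GGAGGUAGACAGAAUGCCAA	1	14.65	LOC107482128	Adu-F-box only protein 6	Cleavage
1			1k	GGAGGUAGACAGAAUGCCAA	1	15.63	LOC105133704	Peu-F-box only protein 6-like (1)	Cleavage
1			1k	GGAGGUAGACAGAAUGCCAA	1	16.33	LOC105123018	Peu-F-box only protein 6-like (2)	Cleavage
2	vvi-miR394a;vvi-miR394c;mes-miR394c	UUGGCAUUCUGUCCACCUCCAU	2	AAGGAGGUUGACAGAAUGCCAA	1	16.82	LOC100242085	Vvi-F-box family protein	Cleavage
3	ptc-miR394a-3p;ptc-miR394b-3p	CUGUUGGUCUCUCUUUGUAA	3	UUACAAAGAGAGACCAACAG	0	17.4	POPTR_0002s11320g	Ptc-Hypo1 (DUF1005)	Cleavage
4	gma-miR394a-3p	AGCUCUGUUGGCUACACUUU	4	UGAGUGCAGCCAGCAGAGCU	3	14.74	LOC100306608	Gma-Unch (DUF3774)	Cleavage
5	zma-miR394a-3p;zma-miR394b-3p;ata-miR394-3p	AGGUGGGCAUACUGCCAAUG	5	CAUUGGCAGUAUGCCCACCU	0	27.31	LOC100383214	Zma-Uncharacterized 2	Cleavage
6	sly-miR394-3p;gma-miR394b-3p	AGGUGGGCAUACUGUCAAC	NA	NA	NA	NA	NA	NA	NA
7	ath-miR394b-3p;aly-miR394a-3p	AGGUGGG[C/U]AUACUGCCAAUA	NA	NA	NA	NA	NA	NA	NA
8	aly-miR394b-3p	AGGUGGACAUAUUGCCAACA	8	CGUUGGUAAUAUGUCUGCCU	2.5	20.27	XM_002894202	Aly-Hypo (Pectinesterase inhibitor domain)	Cleavage
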
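species	gene_id	mir_id	start	end	mfe_kcal_mol	mature_seq	flag
Arachis duranensis	LOC107481607	adu-miR394	314	467	-63.37	UUGGCAUUCUGUCCACCUCC
Arachis ipaensis	LOC107634751	aip-miR394	340	495	-71.4	UUGGCAUUCUGUCCACCUCC
Camelina sativa	LOC104740735	csa-miR394a	509	666	-77.2	UUGGCAUUCUGUCCACCUCC
Camelina sativa	LOC104756391	csa-miR394b	408	555	-70.7	UUGGCAUUCUGUCCACCUCC
Camelina sativa	LOC104702369	csa-miR394c	544	692	-58.2	UUGGCAUUCUGUCCACCUCC
Cucumis sativus	LOC105435326	cst-miR394a	285	429	-51.9	UUGGCAUUCUGUCCACCUCC
Cucumis sativus	LOC105434629	cst-miR394b	196	350	-53.9	UUGGCAUUCUGUCCACCUCC
Erythranthe guttatus	LOC105950700	egu-miR394	248	407	-53.3	UUGGCAUUCUGUCCACCUCC
Eucalyptus grandis	LOC104450295	era-miR394	213	370	-52	UUGGCAUUCUGUCCACCUCC
Fragaria vesca	LOC105349875	fve-miR394	538	675	-57.5	UUGGCAUUCUGUCCACCUCC
Ipomoea nil	LOC109181078	ini-miR394	524	681	-67.1	UUGGCAUUCUGUCCACCUCC
Juglans regia	LOC108984513	jre-miR394	507	663	-64.8	UUGGCAUUCUGUCCACCUCC
Musa acuminata	LOC108951711	mac-miR394	155	327	-73.6	UUGGCAUUCUGUCCACCUCC	window_exceeds_170nt_as_printed
Nelumbo nucifera	LOC109115150	nnu-miR394	562	718	-46.1	UUGGCAUUCUGUCCACCUCC
Nicotiana tomentosiformis	LOC104110977	nto-miR394	188	326	-49.3	UUGGCAUUCUGUCCACCUCC
Populus euphratica	LOC105109932	peu-miR394a	1175	1323	-70.7	UUGGCAUUCUGUCCACCUCC
Raphanus sativus	LOC108816492	rsa-miR394a	108	261	-58.5	UUGGCAUUCUGUCCACCUCC
Raphanus sativus	LOC108816348	rsa-miR394b	117	270	-57.4	UUGGCAUUCUGUCCACCUCC
Raphanus sativus	LOC108816010	rsa-miR394c	1742	1842	-40	UUGGCAGUAUGCCCACCUCC	sequence_conflicts_with_table3_cluster1_as_printed
Populus euphratica	LOC105137284	peu-miR394b	1196	1344	-65	UUGGCAUUCUGUCCACCUCC
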
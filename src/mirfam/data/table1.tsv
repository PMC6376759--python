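mirbase_id	species	n_5p	n_3p	total
ahy-miR394	Arachis hypogaea	1	0	1
aly-miR394	Arabidopsis lyrata	2	2	4
ata-miR394	Aegilops tauschii	1	1	2
ath-miR394	Arabidopsis thaliana	2	1	3
atr-miR394	Amborella trichopoda	1	0	1
bdi-miR394	Brachypodium distachyon	1	0	1
bna-miR394	Brassica napus	2	0	2
cca-miR394	Cynara cardunculus	1	0	1
cme-miR394	Cucumis melo	2	0	2
cpa-miR394	Carica papaya	2	0	2
csi-miR394	Citrus sinensis	1	0	1
ghr-miR394	Gossypium hirsutum	2	0	2
gma-miR394	Glycine max	7	2	9
lus-miR394	Linum usitatissimum	2	0	2
mdm-miR394	Malus domestica	2	0	2
mes-miR394	Manihot esculenta	2	0	2
nta-miR394	Nicotiana tabacum	1	0	1
osa-miR394	Oryza sativa	1	0	1
ppe-miR394	Prunus persica	2	0	2
ptc-miR394	Populus trichocarpa	2	2	4
sbi-miR394	Sorghum bicolor	2	0	2
sly-miR394	Solanum lycopersicum	1	1	2
ssl-miR394	Salvia sclarea	1	0	1
tcc-miR394	Theobroma cacao	2	0	2
vvi-miR394	Vitis vinifera	3	0	3
zma-miR394	Zea mays	2	2	4
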
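taxon	common_name	group	origin	po_percent	fo_percent	mass_kg
Bos taurus	cattle	ungulate	domestic	24.32	45	167
Capra hircus	goat	ungulate	domestic	8.11	15	26
Ovis aries	sheep	ungulate	domestic	2.70	5	27
Canis lupus familiaris	dog	carnivore	domestic	2.70	5	12
Gallus gallus	domestic fowl	bird	domestic	13.51	25	0.78
Muntiacus vaginalis	barking deer	ungulate	wild	16.22	30	18
Rusa unicolor	sambar deer	ungulate	wild	5.41	10	212
Sus scrofa	wild boar	ungulate	wild	2.70	5	38
Macaca mulatta	rhesus macaque	primate	wild	2.70	5	6
Aquila spp.	eagle	bird	wild	2.70	5	3
Lophura leucomelanos	kalij pheasant	bird	wild	2.70	5	0.89
Mus spp.	mouse	rodent	wild	13.51	25	0.5
Hystrix spp.	porcupine	rodent	wild	2.70	5	1.5
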
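taxon	common_name	group	origin	po_percent	fo_percent	mass_kg
Bos taurus	cattle	ungulate	domestic	1.32	3.85	167
Bandicota spp.	bandicoot rat	rodent	wild	2.63	7.69	0.58
Cricetomys spp.	giant pouched rat	rodent	wild	3.95	11.54	1.25
Mus spp.	mouse	rodent	wild	21.05	61.54	0.5
Niviventer spp.	niviventer rat	rodent	wild	25.00	73.08	0.08
Rattus spp.	rattus rat	rodent	wild	21.05	61.54	0.15
Petaurista spp.	giant flying squirrel	rodent	wild	2.63	7.69	1.65
Episoriculus spp.	brown-toothed shrew	shrew	wild	3.95	11.54	0.01
Arborophila torqueola	hill partridge	bird	wild	1.32	3.85	0.31
Oenanthe spp.	wheatear	bird	wild	1.32	3.85	0.02
Pellorneum ruficeps	puff-throated babbler	bird	wild	1.32	3.85	0.03
Lophura leucomelanos	kalij pheasant	bird	wild	1.32	3.85	0.89
Ptychidio spp.	carp fish	fish	wild	1.32	3.85	2.5
Schizothorax spp.	snowtrout	fish	wild	2.63	7.69	2.5
Muntiacus vaginalis	barking deer	ungulate	wild	9.21	26.92	18
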
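# Genomically integrated SOD1/tubulin western densitometry for the same attenuators,
# percent of the un-attenuated control; published means/SEMs.
hairpin_id	delta_g_kcal_mol	promoter	mean_percent	sem	n
control		CBh	100.0	0.0	3
HP06	-30.1	CBh	54.56	2.85	3
HP13	-34.0	CBh	35.27	1.46	3
HP22	-38.9	CBh	8.14	0.11	3
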
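# Plasmid-based GFP/RFP ratiometry of SOD1-replacement attenuators (CBh promoter),
# percent of the un-attenuated control; published means/SEMs for hairpins #6/#13/#22.
hairpin_id	delta_g_kcal_mol	promoter	mean_percent	sem	n
control		CBh	100.0	0.0	3
HP06	-30.1	CBh	58.05	2.58	3
HP13	-34.0	CBh	34.91	1.40	3
HP22	-38.9	CBh	9.10	0.64	3
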
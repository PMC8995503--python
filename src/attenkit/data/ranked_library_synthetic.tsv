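# SYNTHETIC ranked-library fixture: performance-ranked attenuation values for a
# 9 CBh / 9 EF1a / 7 TetOn panel. All numbers below are synthetic placeholders
# generated to be monotone and plausible; only calibration_sod1_*.tsv carries
# published measurements.
hairpin_id	delta_g_kcal_mol	promoter	mean_percent	sem	n
control		CBh	100.0	0.0	3
HP02	-28.2	CBh	71.4	3.1	3
HP04	-29.3	CBh	64.8	2.9	3
HP06	-30.1	CBh	58.05	2.58	3
HP09	-31.8	CBh	49.6	2.4	3
HP11	-32.9	CBh	42.3	2.1	3
HP13	-34.0	CBh	34.91	1.40	3
HP16	-35.7	CBh	26.5	1.3	3
HP19	-37.3	CBh	17.2	1.0	3
HP22	-38.9	CBh	9.10	0.64	3
HP02	-28.2	EF1a	68.9	3.3	3
HP04	-29.3	EF1a	61.7	3.0	3
HP06	-30.1	EF1a	55.2	2.7	3
HP09	-31.8	EF1a	47.1	2.3	3
HP11	-32.9	EF1a	39.8	2.0	3
HP13	-34.0	EF1a	32.6	1.6	3
HP16	-35.7	EF1a	24.0	1.2	3
HP19	-37.3	EF1a	15.5	0.9	3
HP22	-38.9	EF1a	8.3	0.5	3
HP04	-29.3	TetOn	63.1	3.4	3
HP06	-30.1	TetOn	56.8	2.9	3
HP09	-31.8	TetOn	48.0	2.5	3
HP13	-34.0	TetOn	33.9	1.8	3
HP16	-35.7	TetOn	25.1	1.4	3
HP19	-37.3	TetOn	16.3	1.1	3
HP22	-38.9	TetOn	8.8	0.7	3
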
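# provenance: DNA free energies at 37 C (SantaLucia 1998 / Mathews lab set), as distributed with ViennaRNA 2.7.2 (dna_mathews2004.par)
# units: kcal/mol at 37 C
# closing_pair XY closes the loop (X 5' side); x/y are the first/last loop bases
# terminal_end_penalty	0.00
closing_pair	x	y	dg
AT	A	A	-0.70
AT	A	C	-0.30
AT	A	G	-0.50
AT	A	T	0.00
AT	C	A	-0.60
AT	C	C	-0.20
AT	C	G	0.00
AT	C	T	-0.30
AT	G	A	-0.60
AT	G	C	0.00
AT	G	G	-0.40
AT	G	T	-0.50
AT	T	A	0.00
AT	T	C	-0.30
AT	T	G	-0.50
AT	T	T	-0.40
CG	A	A	-1.00
CG	A	C	-0.80
CG	A	G	-0.90
CG	A	T	0.00
CG	C	A	-0.80
CG	C	C	-0.50
CG	C	G	0.00
CG	C	T	-0.70
CG	G	A	-1.00
CG	G	C	0.00
CG	G	G	-0.90
CG	G	T	-1.00
CG	T	A	0.00
CG	T	C	-0.60
CG	T	G	-0.90
CG	T	T	-0.90
GC	A	A	-1.00
GC	A	C	-0.70
GC	A	G	-0.80
GC	A	T	0.00
GC	C	A	-1.00
GC	C	C	-0.60
GC	C	G	0.00
GC	C	T	-0.70
GC	G	A	-1.00
GC	G	C	0.00
GC	G	G	-1.00
GC	G	T	-0.80
GC	T	A	0.00
GC	T	C	-0.60
GC	T	G	-0.90
GC	T	T	-0.90
TA	A	A	-0.60
TA	A	C	-0.40
TA	A	G	-0.50
TA	A	T	0.00
TA	C	A	-0.50
TA	C	C	-0.20
TA	C	G	0.00
TA	C	T	-0.50
TA	G	A	-0.60
TA	G	C	0.00
TA	G	G	-0.40
TA	G	T	-0.50
TA	T	A	0.00
TA	T	C	-0.30
TA	T	G	-0.60
TA	T	T	-0.30
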
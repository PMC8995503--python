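# provenance: Turner 2004 RNA free energies at 37 C (Mathews et al. 2004), as distributed with ViennaRNA 2.7.2 (rna_turner2004.par)
# units: kcal/mol at 37 C
# closing_pair XY closes the loop (X 5' side); x/y are the first/last loop bases
# terminal_end_penalty	0.50
closing_pair	x	y	dg
AU	A	A	-0.30
AU	A	C	-0.50
AU	A	G	-0.30
AU	A	U	-0.50
AU	C	A	-0.10
AU	C	C	-0.20
AU	C	G	-0.10
AU	C	U	-0.20
AU	G	A	-1.20
AU	G	C	-0.50
AU	G	G	-1.10
AU	G	U	-0.50
AU	U	A	-0.10
AU	U	C	-0.30
AU	U	G	-0.10
AU	U	U	-1.20
CG	A	A	-1.50
CG	A	C	-1.50
CG	A	G	-1.40
CG	A	U	-1.50
CG	C	A	-1.00
CG	C	C	-1.10
CG	C	G	-1.00
CG	C	U	-0.80
CG	G	A	-2.30
CG	G	C	-1.50
CG	G	G	-2.40
CG	G	U	-1.50
CG	U	A	-1.00
CG	U	C	-1.40
CG	U	G	-1.00
CG	U	U	-2.10
GC	A	A	-1.10
GC	A	C	-1.50
GC	A	G	-1.30
GC	A	U	-1.50
GC	C	A	-1.10
GC	C	C	-0.70
GC	C	G	-1.10
GC	C	U	-0.50
GC	G	A	-2.50
GC	G	C	-1.50
GC	G	G	-2.20
GC	G	U	-1.50
GC	U	A	-1.10
GC	U	C	-1.00
GC	U	G	-1.10
GC	U	U	-1.60
UA	A	A	-0.50
UA	A	C	-0.30
UA	A	G	-0.50
UA	A	U	-0.30
UA	C	A	-0.20
UA	C	C	-0.10
UA	C	G	-0.20
UA	C	U	0.00
UA	G	A	-1.50
UA	G	C	-0.30
UA	G	G	-1.50
UA	G	U	-0.30
UA	U	A	-0.20
UA	U	C	-0.10
UA	U	G	-0.20
UA	U	U	-0.90
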
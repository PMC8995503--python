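# provenance: DNA free energies at 37 C (SantaLucia 1998 / Mathews lab set), as distributed with ViennaRNA 2.7.2 (dna_mathews2004.par)
# units: kcal/mol at 37 C
# stack code WXYZ = top strand 5'-WX-3' stacked on bottom strand 5'-YZ-3' (pairs W:Z and X:Y); canonical under 180-degree rotation
stack	dg
AATT	-1.00
ACGT	-1.40
AGCT	-1.30
ATAT	-0.90
CATG	-1.50
CCGG	-1.80
CGCG	-2.20
GATC	-1.30
GCGC	-2.20
TATA	-0.60
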
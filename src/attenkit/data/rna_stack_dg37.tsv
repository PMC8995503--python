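# provenance: Turner 2004 RNA free energies at 37 C (Mathews et al. 2004), as distributed with ViennaRNA 2.7.2 (rna_turner2004.par)
# units: kcal/mol at 37 C
# stack code WXYZ = top strand 5'-WX-3' stacked on bottom strand 5'-YZ-3' (pairs W:Z and X:Y); canonical under 180-degree rotation
stack	dg
AAUU	-0.90
ACGU	-2.20
AGCU	-2.10
AUAU	-1.10
CAUG	-2.10
CCGG	-3.30
CGCG	-2.40
GAUC	-2.40
GCGC	-3.40
UAUA	-1.30
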
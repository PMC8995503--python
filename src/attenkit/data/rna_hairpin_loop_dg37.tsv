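# provenance: Turner 2004 RNA free energies at 37 C (Mathews et al. 2004), as distributed with ViennaRNA 2.7.2 (rna_turner2004.par)
# units: kcal/mol at 37 C
# loops longer than 30 nt: dg(n) = dg(30) + 1.07856 * ln(n/30)
loop_length	dg
3	5.40
4	5.60
5	5.70
6	5.40
7	6.00
8	5.50
9	6.40
10	6.50
11	6.60
12	6.70
13	6.80
14	6.90
15	6.90
16	7.00
17	7.10
18	7.10
19	7.20
20	7.20
21	7.30
22	7.30
23	7.40
24	7.40
25	7.50
26	7.50
27	7.50
28	7.60
29	7.60
30	7.70
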
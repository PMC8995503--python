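# provenance: DNA free energies at 37 C (SantaLucia 1998 / Mathews lab set), as distributed with ViennaRNA 2.7.2 (dna_mathews2004.par)
# units: kcal/mol at 37 C
# loops longer than 30 nt: dg(n) = dg(30) + 1.07856 * ln(n/30)
loop_length	dg
3	3.40
4	3.40
5	3.50
6	4.20
7	4.20
8	4.20
9	4.30
10	4.40
11	4.50
12	4.60
13	4.70
14	4.80
15	5.00
16	5.10
17	5.20
18	5.30
19	5.40
20	5.50
21	5.60
22	5.70
23	5.80
24	5.90
25	6.00
26	6.10
27	6.20
28	6.30
29	6.40
30	6.50
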
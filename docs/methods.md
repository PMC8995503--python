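# Methods

`attenkit` implements the computational half of a knockdown-replacement
(KDR) workflow: designing a graded-stability library of 5′ UTR hairpin
"attenuators", scoring their folding free energy, selecting a uniformly
spaced panel, calibrating attenuation against measured
percent-of-control expression, and quantifying that attenuation from
two-channel fluorescence images. This note records the models,
parameter choices and numerical conventions behind each stage, and what
the synthetic validation does and does not demonstrate.

## The attenuator model

A stem-loop placed in the 5′ UTR just upstream of the start codon
sterically hinders scanning/initiation, reducing translation of the
downstream gene in inverse relation to the hairpin's thermodynamic
stability. Every insert in the library shares one architecture:

```
5'- GCGGCCG · stem · TATACT · revcomp(stem) · CGGCCGC -3'
    base arm  ≤11 nt   loop                    base arm
```

The constant 7-nt base arm (seven of the eight NotI recognition bases)
anchors the helix with G/C pairs and keeps the insert compatible with
AgeI/NotI cloning; the 6-nt TATACT loop is shared by all designs so that
only the variable stem differentiates them. Insert length is therefore
`2·(7 + stem length) + 6` nt: stems of 5–9 bp give the 30/32/34/36/38-nt
length classes.

Variable stems are G/C-rich with a prescribed number of A/T bases
(default exactly one), which maximizes stability per nucleotide while
keeping composition uniform across the library. Grading downward is
done by *trimming*: repeatedly deleting the loop-adjacent ("innermost")
stem pair, i.e. the 3′-most base of the 5′ stem arm, whose partner
disappears implicitly on assembly. After pooling full-length stems with
all trims, exact duplicates collapse (keeping the lexicographically
first provenance) and stems with zero A/T bases are dropped — an
uninterrupted G/C helix folds far outside the useful range.

Defaults in `DesignConstraints`: stem length 11 nt, one A/T base,
self-complementarity window 4 nt, trim floor 1 nt, forbidden motifs =
the five restriction sites the construct geometry uses (AgeI, NotI,
SbfI, EcoRI, XhoI), screened on both strands. The original
EGNAS-configured generator for this design space reported 1,360
full-length stems and 5,729 structures after trimming/dedup over
−15.7…−48.2 kcal/mol; its exact configuration (its forbidden-motif
list and self-complementarity rule) was distributed as supplementary
config files and is not reconstructible, so those numbers are exposed
only as a logged diagnostic (`design.library_diagnostics`), never
asserted. At the defaults above this package enumerates 22,048
full-length stems and a 40,454-member scored library spanning −49.4 to
−15.9 kcal/mol — the same span to within ~1 kcal/mol.

## Free-energy evaluation

Designed inserts are perfect hairpins, so their fixed-structure folding
free energy at 37 °C decomposes additively:

ΔG°₃₇ = Σ stacks + loop-initiation(loop length) + terminal mismatch
(closing pair, first/last loop bases) [+ helix-end A:U penalty].

Parameters are the Turner 2004 RNA set (Mathews lab), transcribed into
packaged TSVs from the reference distribution with a provenance string;
a DNA set (SantaLucia/Mathews 1999-style) is selectable. The hairpin
acts in mRNA, so the default is RNA rules with T read as U. Loops
longer than the tabulated 30 nt use the standard Jacobson–Stockmayer
extrapolation (coefficient 1.07856 kcal/mol); loops under 3 nt are
physically disallowed and raise.

Scope is deliberately restricted to isolated stem-loops: no bulges,
internal loops, multiloops, dangles or coaxial stacking. Within that
scope, `hairpin_dG` reproduces the reference fixed-structure evaluator
(`RNAeval`) exactly (RMS 0.0 kcal/mol over 100 random designs in the
test suite, tolerance 0.5). Two definitional choices the "initial dG"
convention leaves open are exposed as configuration rather than
guessed: nucleic-acid kind (RNA default) and whether the loop-closing
terminal mismatch is included (default on, the standard hairpin rule;
`use_terminal_mismatch=False` drops it).

## Alternative-fold checking

`max_pairing_fold` is a Nussinov-style dynamic program returning a
maximum-cardinality non-crossing Watson–Crick pairing with a minimum
loop of 3 nt. The natural secondary objective — prefer the longest
contiguous helix among maximum pairings — does not decompose over
subintervals, so the implemented tie-break maximizes the number of stacked pair adjacencies (which
decomposes exactly and strongly favors long helices), then takes the
lexicographically smallest pair list via a deterministic traceback —
repeated runs always report the same structure.

`verify_intended_fold` asks whether the designed stem achieves the
maximal pair count and whether any ≥4-pair helix disjoint from the
intended pairing (same bases in a different register count) can form.
The maximality check uses a 4-nt minimum loop: with a bare 3-nt
minimum, the TATACT loop itself always admits one lone A:T pair across
a 3-nt gap, inflating every alternative count by one although a lone
pair over a minimal loop is not a stable competitor.

## Panel selection and calibration statistics

The useful attenuation window is roughly −27 to −40 kcal/mol (≈50 %
down to ≈10 % of un-attenuated expression). `select_panel` formalizes
the manual "uniform increments" subset choice: k ideal grid points are
placed evenly across the range and distinct library members are
assigned to them minimizing total |ΔG| deviation. Because pool and
grid are both one-dimensional, an optimal assignment is non-crossing
and is found exactly by an O(n·k) dynamic program; ties prefer the more
stable member. On this package's dense library the 24-member panel
comes out with a 0.557 kcal/mol mean step (ideal grid 13/23 ≈ 0.565);
an independently printed probe pair of the measured panel —
rank 6 at −30.1 and rank 22 at −38.9 — implies 0.55 per step.

Replicate statistics use the normal approximation: SEM = sample SD/√n,
95 % CI half-width = 1.96·SEM (z configurable; 1.96 is used because the
published CI/SEM ratios are ≈1.96). The ΔG→attenuation curve itself is
empirical and non-linear, so ranking and target matching operate on
*measured* percent-of-control tables (`CalibrationTable`), never on a
fitted model: `rank_by_performance` sorts by measured mean within
promoter, `choose_attenuator` returns the entry nearest a target
percentage (distance ties go to the less-attenuated entry; 100 %
returns the control), and `predicted_vs_observed` checks whether
integrated (viral) expression lies within the plasmid-based 95 % CI per
hairpin. The packaged plasmid/integrated fixtures carry the published
printed means/SEMs for the −30.1/−34.0/−38.9 kcal/mol SOD1-replacement
conditions; `ranked_library_synthetic.tsv` is synthetic filler for the
full ranked panel, labelled as such in the file.

## Ratiometry

Attenuation is measured as mean per-pixel GFP/RFP over a
background-thresholded mask, mirroring the acquisition pipeline the
package targets (948×948 16-bit composites, 10×10 tiling, uniform
manual thresholds, >1,000 cells per replicate). Numerical choices:

- **Tiling**: floor(H/n)×floor(W/n) tiles; remainder rows/columns are
  discarded from the bottom/right (948→100 tiles of 94×94). Tiling is
  lossless modulo that crop.
- **Mask**: both channels must clear their thresholds by default (a
  sub-background green pixel contributes an unreliable ratio); a
  red-only mode exists because the original software's behavior is
  unspecified.
- **Estimator**: per-pixel mean of ratios is primary ("pixel-wise
  comparison"); Σgreen/Σred is available as a flag, again because the
  original choice is unspecified.
- 16-bit data are processed as float64; no background subtraction
  beyond thresholding; an empty mask is a no-signal result, not an
  error.

The synthetic generator paints non-overlapping random ellipses ("cells")
with per-cell log-normal red amplitude (median 18,000 counts, σ=0.35 —
sparse bright transfectants well clear of background), green =
fraction × red × (1 + N(0, 0.08)) per pixel, and N(120, 20) camera
background on both channels, clipped to 16 bits. Everything is driven
by one explicit seed; identical scenes give bit-identical TIFFs. It
emulates channel-correlated intensities, expression heterogeneity and
dark-background thresholding; it does **not** emulate cell overlap and
clumping, illumination-field inhomogeneity, bleed-through, or
saturation — so closed-loop recovery demonstrates the estimator and
masking logic are unbiased under the stated noise model, not that real
micrographs are free of those systematics. Validation scenes use
256×256 fields with 14 cells (≈10,000 foreground pixels, comfortably
above the 1,000-pixel averaging scale); across the 10–100 %
attenuation regime, percent-of-control is recovered within ±3 points in
100/100 seeded runs per condition.

## Construct assembly

`assemble_construct` concatenates parts in the fixed transcript order
(promoter, attenuator, Kozak, rescue, then optionally IRES + reporter,
then the miR-E cassette) into a Biopython `SeqRecord` with one feature
per part, 0-based half-open, top strand; the GenBank writer handles the
1-based convention. The attenuator part is the `assemble_hairpin`
insert verbatim, joined to the Kozak part by plain concatenation — the
published base arm "shares six nucleotides" with a Kozak consensus, but
the exact junction overlap is not documented, so no overlap is guessed.
Site validation scans both strands (palindromes counted once per
position) and enforces the cloning geometry: NotI/SbfI absent inside
the rescue gene, EcoRI/XhoI absent inside a user-supplied shRNA.
Backbone sequences (vector deposits) are not shipped; the module
validates user-supplied parts.

## Problem sizes and determinism

The default test suite and the acceptance script regenerate everything
programmatically: the full 40k-member library build (~6 s), 100-design
reference-evaluator comparisons, 500-sequence brute-force fold checks,
200 panel-assignment instances against exhaustive search, and 400
synthetic ratiometry scenes at 256². All randomness flows through
explicit seeds; there is no hidden global random state.

## Known limitations

- The energy model evaluates the intended fold only; a design whose
  best *thermodynamic* fold contains a bulge would be mis-scored —
  mitigated by `verify_intended_fold`, which flags competing registers.
- Enumeration counts depend on screening rules that the original
  generator defined in unavailable config files; only the ΔG span is
  comparable.
- `choose_attenuator` interpolates on measured ranks; it cannot
  extrapolate below the strongest measured attenuator.
- The ratiometry CLI reads single-channel TIFF pairs; proprietary
  microscope containers must be converted first.
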
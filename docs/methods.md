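# Methods

## Coordinate system

All cross-gene position equivalence uses Sprinzl numbering: labels
"1"–"76" for the canonical cloverleaf, insertion labels "17a", "20a",
"20b" in the D-loop and "e1"… for variable-arm extensions of long-arm
(Leu/Ser-type) tRNAs. Labels are strings and are never used
arithmetically; insertion labels sort immediately after their base
label.

The column → label map is derived once per alignment from the consensus
secondary-structure line (Stockholm `#=GC SS_cons`, or a sidecar string
for aligned FASTA). Base pairs are recovered by bracket matching and
grouped into helices of contiguously stacked pairs; helices are
assigned, in 5′ order, to the acceptor, D, anticodon, optional
variable-arm and T stems, and loop/linker columns are numbered against
the canonical cloverleaf layout. Deterministic conventions for
non-canonical layouts:

- **D-loop**: a loop of 8 columns reads 14–21; 9, 10 or 11 columns add
  17a, then 20a, then 20b; shorter loops truncate from the end.
- **Anticodon and T loops**: with more than 7 columns the first six take
  the first six labels, the last column takes the final label, and the
  middle columns stay unmapped. This places intron columns — which in
  eukaryotic tRNA genes always fall between positions 37 and 38 —
  outside the map without special-casing, both for genes that carry the
  intron and for intronless genes aligned against the same columns.
- **Variable region**: five columns read 44–48; extra columns (or an
  embedded variable-arm helix) take e-labels between 47 and 48.

Columns that receive no label are excluded from every analysis.
Alignment columns are 0-based half-open internally and 1-based in all
files; `T` on input is silently converted to `U`; `N` is accepted and
propagates to UNDEFINED classifications.

Mature sequences exclude intron columns; *transcript identity*
additionally excludes positions 74–76, because the genes are genomic
and the 3′ CCA is added enzymatically. Unique-transcript counting and
the per-anticodon mean/SD statistics operate on this CCA-less mature
sequence. Gene sets are filtered at a bit score of ≥ 55 (inclusive)
before any conservation analysis, the conventional boundary between
likely-functional genes and pseudogenes.

## Pair classification

The class of a stem opposition is a pure function of the ordered pair
(5′ base, 3′ base), the 5′ base being the strand with the lower Sprinzl
number: four Watson–Crick classes, two wobble classes (GoU ≠ UoG —
the two orientations are structurally distinct), OTHER for the ten
remaining concrete pairs (retained verbatim, without geometric
subtyping), and UNDEFINED when either side is a gap or N. Pseudouridine
is not modelled; U stands for U/Ψ since the modification does not
prevent wobble pairing.

Each gene's profile covers all 21 canonical stem positions
(AA 1:72…7:66, D 10:25…13:22, AC 27:43…31:39, T 49:65…53:61) plus a
fixed tertiary catalogue checked as pass/deviation: the U8:A14:A21
triple, the long-range 15:48 pair (accepted as G15:C48 or A15:U48),
the trans U54oA58 pair, G18/G19, U55, C56, the purine at 9 and U33.
Known biological deviations (C9 in His tRNAs, C33 in initiator Met)
are reported as deviations, not errors.

## Consensus motifs

Per group and stem, the 5′-strand consensus is built column-wise: the
IUPAC letter is the smallest degenerate set covering every base whose
within-group frequency exceeds the inclusion floor (default 0.05,
suppressing rare variants the way published motif tables do). Groups
are keyed by level (isotype / isoacceptor-set / isodecoder) and a clade
scope. Long-arm groups additionally report the first and last terminal
triplets of the variable-arm extension.

## Conservation map and census

A wobble orientation at a position is conserved for a group when the
fraction of informative genes (UNDEFINED pairs excluded from the
denominator) carrying exactly that orientation is ≥ τ in **every**
required clade. τ defaults to 0.9: high enough to mean "characteristic
of the family", tolerant of an occasional divergent isodecoder; no
published numeric threshold exists for this call, so τ is an explicit
parameter. Positions 31:39 and 52:62, where wobble pairs occur only
rarely and never attached to a particular tRNA type, are flagged and
excluded from the census (they remain available under a `rare` flag).

The census counts distinct positions with any conserved wobble, with
GoU, with UoG, with both orientations (necessarily via different
groups), with a single orientation, and 2 × (positions with any) as the
number of position–orientation possibilities. The identities
`any = GoU + UoG − both` and `single = any − both` hold on every map and
are property-tested.

A packaged TSV transcribes the reference catalogue of conserved wobble
orientations in mammalian/insect tRNAs (one row per position ×
orientation × group, clade scope M/I). Rows whose group label is not
identified in the transcribed source carry isotype "."; the position
census — 15 of 21 positions, 10 GoU, 11 UoG, 6 both, 9 single — is
unaffected by those labels.

## Matched variation tests

**SNP disruption.** A SNP at either strand of a pair disrupts it when
substituting the alternate allele against the partner's reference base
moves the pair out of its current category ({GoU, UoG} for wobble pairs;
the four WC pairs for controls). Allele frequencies above 0.5 are folded
to minor-allele frequencies before use. For each conserved entry, the
focal side aggregates, over group genes carrying the conserved
orientation, each gene's highest disrupting-SNP frequency; the control
side does the same over genes of *other* isotypes whose pair at that
position is Watson–Crick (genes of the focal isotype are excluded
entirely). Two aggregations are provided — "most-common" (maximum;
default, following the most-common-SNP formulation) and "average"
(mean; an alternative formulation used in some presentations of this
comparison). Entries lacking focal or control observations are skipped
with a logged reason. When an isotype-level entry recurs in one of its
isodecoder groups, comparisons are deduplicated to one per (isotype,
position, orientation), preferring the broader group — matching the
"per isotype and position" accounting of such analyses.

**Sign test.** Ties are excluded; the remaining signs are Bernoulli(½)
under the null. One-sided p is the exact upper binomial tail; two-sided
p doubles the smaller tail, capped at 1; an empty comparison set gives
p = 1. The implementation (scipy binomial tails) is tested against an
independent oracle enumerating all 2ⁿ sign vectors for n ≤ 12. Note
that for 20 positive of 24 the exact one-sided tail is
12951/2²⁴ ≈ 7.72 × 10⁻⁴ (two-sided ≈ 1.54 × 10⁻³); a previously
printed bound of 6.3 × 10⁻⁴ for this configuration is not reproducible
as an exact binomial tail and is treated as a documented discrepancy —
this package always reports the exact values.

**Score comparison.** Per gene, the value at a pair is the minimum
per-position conservation score over its two strands; focal and control
sides are formed as above and aggregated by mean (default). The sign is
+1 when the focal (wobble) side scores higher. For 14 positive of 23
the exact one-sided tail is 0.2024, computed here from the same sign
test.

## Synthetic data generator

The generator emulates the study conditions end to end and is itself
first-class, tested code. Defaults (the standard conditions for the
test-suite and acceptance runs):

- **Design**: 4 species — two Mammalia, two Insecta — × 23 isodecoders
  (20 isotypes) × 3 gene copies = 276 genes on one shared alignment
  (90 columns: the 76-column canonical layout plus a 14-column intron
  block between 37 and 38, carried by the Arg-UCU genes).
- **Stems**: per-isotype IUPAC templates mirroring published consensus
  motifs (Ala AA `GGGGUUG`, Gln `GGYYCCA`, Asp AC `CCCGC`, …); each
  gene samples concrete bases within the template letters, with
  compensatory Watson–Crick 3′ bases so stems stay paired.
- **Planted truth**: 24 (group, position, orientation) wobble entries
  covering all four stems at conservation rate 1.0 (non-conforming
  genes revert to WC); a plant whose required 5′ base falls outside the
  template letter is a configuration error.
- **Loops**: a fixed single-stranded template satisfying every tertiary
  expectation, with point mutations at rate 0.02 per loop position
  (anticodon excluded).
- **Pseudogenes**: fraction 0.1; three randomly broken stem pairs and a
  bit score from N(42, 6) clipped below 55, versus N(72, 6) clipped
  above 55 for functional genes — the distributions never straddle the
  threshold, so the ≥ 55 filter recovers the functional set exactly.
- **SNPs**: per occupied position, probability 0.25 of one SNP;
  alternate allele uniform over the three non-reference bases; MAF from
  Beta(1, 50) (mean ≈ 0.02) when the position belongs to a wobble pair
  in that gene, Beta(2, 20) (mean ≈ 0.09) otherwise. A Beta shape-b of
  0 denotes a point mass at the shape-a value (used for tie/degenerate
  scenarios).
- **Scores**: N(2.0, 0.5) at wobble-pair strands, N(0.5, 0.5)
  elsewhere, per gene-position.

All draws come from one `numpy` generator seeded by the caller; equal
seeds give byte-identical outputs. What the generator does **not**
emulate: phylogenetic correlation between species (species are
exchangeable replicates with clade labels), linkage between SNPs,
genomic context (segmental duplications, transcription), covariance
-model scoring (bit scores are drawn, not computed) and base
modifications. Passing tests on this data therefore demonstrate the
correctness of the pipeline's logic and the detectability of planted
effects under idealised sampling — not that real tRNA data meet these
assumptions.

## Numerical and design choices

- Sign-test power is assessed on the full pipeline: under the default
  MAF separation and 24 comparisons the two-sided test rejects at
  α = 0.05 in ≥ 90% of 200 seeded replicates (observed: 100%).
- Null calibration is assessed through the score channel with equal
  class distributions, where the per-comparison sign probability is ½
  by exchangeability of mean aggregation; the rejection rate over 400
  seeds is required to lie in [0.01, 0.10] (observed ≈ 0.02 — the
  discrete exact test is conservative). The SNP channel's
  maximum-aggregation over unequal focal/control pool sizes is not
  ½-calibrated under equal distributions (the maximum of more draws is
  stochastically larger), so calibrating there would conflate design
  imbalance with miscalibration; degenerate point-mass frequencies are
  instead tested to give all ties and p = 1.
- Problem sizes (276 genes, 200 power replicates, 400 calibration
  seeds) were chosen as the smallest design in which every planted
  group retains ≥ 10 functional genes per clade and the Monte-Carlo
  error on a rate estimated from 200–400 replicates (≤ ±0.035 at 95%)
  is small against the acceptance bands.
- Variable-arm pairing (long-arm tRNAs) is represented as optional
  V-positions pairing the first k against the reversed last k arm
  positions (k = 3), sufficient for the terminal-triplet motifs
  reported for Leu/Ser; long arms are off by default in the generator.
- Consensus ties cannot arise: each subset of {A, C, G, U} has exactly
  one IUPAC letter; the letter search order is fixed regardless.
- Unique-gene-count statistics use the sample (n−1) standard deviation,
  0.0 for a single species.

## Known limitations

- Sprinzl assignment trusts the provided consensus structure line; no
  covariance-model alignment is performed, and genes whose true
  structure deviates from the consensus are numbered by the consensus.
- The code-wheel placement uses the GC count of the anticodon triplet
  as the pairing-strength score standing in for a full
  triplet-minihelix free-energy model; only the sector assignment
  (North / intermediate / South) is provided, not a rendered wheel.
- OTHER pairs are not geometrically subtyped; isostericity and 3D
  modelling are out of scope.
- Real-data scale results (primate gene-count tables, population SNP
  and phyloP comparisons) require external genome resources and are
  represented here only by the synthetic surrogates above and the
  exact tail probabilities for the reported comparison counts.
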
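# Methods

This note documents the models and procedures `crl4score` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and gene models

VCF records are 1-based; every internal interval is 0-based half-open.
Gene models are single-transcript (as in a targeted panel design): exons,
CDS, 5'/3' UTRs, and *panel windows* equal to exons padded by a fixed
intronic flank (default 50 bp per side, the panel's capture design).
Multi-allelic VCF records are decomposed into biallelic variants, because
scoring and burden are per-allele.  Location classification tests the REF
span against CDS, then UTRs, then panel windows; anything outside the
windows is flagged `out_of_panel` rather than rejected.  "Coding" means
CDS-overlapping — UTR variants are tallied separately — and location
shares are reported *truncated* (not rounded) to one decimal, so 11/145
prints as 7.5%.  Coding SNVs are subtyped synonymous / missense /
nonsense from the spliced CDS, reverse-complementing alleles on minus-
strand genes.

## The severity rubric

External predictors are never executed; their verdicts arrive as
normalized annotations `(variant, category, verdict, source)` with
verdict in {none, possible, strong} over ten categories
(deleteriousness ensembles, protein effect, splicing, polyadenylation,
TFBS, miRNA binding, CpG island, mRNA structure, enhancer, codon usage).
Consolidation keeps the most severe verdict per (variant, category);
missing categories score 0 — only predicted effects earn points, absence
of a prediction is not missing data.

The default rubric awards 0/1/2 points per category, giving a per-variant
total in 0–20 with a reporting threshold of 10.  The exact published
weighting behind this class of score is not public, so the rubric is a
reconstruction with the same ceiling and is fully file-configurable
(YAML), with validation that `none` always scores 0 and points are
monotone in verdict severity.  One positional modifier is built in:
a splicing-relevant verdict (`possible`) on a variant in or within the
intronic flank of an exon upstream of the first *critical exon* is
promoted to `strong`, because losing such an exon removes everything the
critical exons encode (for Cereblon, the C-terminal drug-binding region
behind exon 10).  The modifier promotes within the 0–2 range rather than
adding bonus points, preserving the ceiling of 20.  Heatmap rows are
ordered by total descending, ties broken lexicographically by variant id,
for determinism.

## Burden and cohort statistics

Default burden weighting is *carrier* (a variant with dosage ≥ 1
contributes once), matching genotype-heatmap presentation of
presence/absence; *dosage* weighting is a flag.  Missing genotypes
contribute nothing and are logged.  Panel-wide sums equal the sum of the
per-gene sums by construction.

Statistical defaults mirror ordinary desk practice for small cohorts:
two-sided pooled-variance Student's t (Welch optional), one-way ANOVA for
the three-group comparison, Pearson chi-square without continuity
correction on contingency tables, with Fisher's exact test always
reported alongside for 2×2 carrier tables, and nominal p-values by
default (Benjamini–Hochberg available as a helper).  When both groups
have zero variance and equal means the t comparison reports t = 0, p = 1.
Location-distribution comparisons with an expected cell below 1 switch to
a margin-conditional Monte-Carlo exact p-value with a warning.
Monomorphic variants are skipped in association testing with a notice.
Rare means MAF strictly below 0.01; supplied frequencies above 0.5 are
folded to the minor allele.

## Sequence-level analyses

**CpG islands.**  Gardiner-Garden–Frommer criteria with a 200-bp window
sliding in steps of 1: a window qualifies if GC ≥ 0.5 and observed /
expected CpG ≥ 0.6, where obs/exp = #CpG / (#C·#G / L); overlapping
qualifying windows are merged into maximal islands.  `N` disqualifies any
window containing it.  All three thresholds and the window length are
parameters.  A variant's island impact is judged by re-running the
detector on the edited sequence and comparing islands within two window
lengths of the variant: created / disrupted / enlarged / shrunk / none,
plus the net bp change.

**Codon usage.**  Tables count codons over one or more CDSs (warnings for
missing ATG/stop; internal stops excluded); within-family relative
frequencies use the standard genetic code, stop codons excluded from
families.  A synonymous swap's verdict compares the dense frequency rank
of alternative vs reference codon within the family, at gene scope (the
gene's own CDS) and genome scope (a supplied table; an approximate
human-like fixture ships with the package, since which genome-wide table
to use is the user's choice).

**Motif disruption.**  JASPAR count matrices (parsed with Biopython) are
smoothed with a pseudocount (default 0.25 per cell) into probabilities;
scoring is log2 odds against a uniform background over the best window
overlapping the variant on either strand, before and after the edit.
Verdicts: *broken* when the reference site scores at or above the
bound-site threshold (default 0.8 × the motif maximum — conservative)
and the alternate falls below; *weakened*/*strengthened* at a ±1-bit
change; *unchanged* otherwise.  Thresholds are parameters.

**Bisulfite.**  The conversion model is complete by default: every
unmethylated C reads T, methylated CpG cytosines are retained; a
conversion-failure rate parameter exists for simulating incomplete
conversion.  Calling inverts the map per CpG cytosine of the original
sequence; any other base at such a position is `uninformative`.
Round-trip (call ∘ convert) is exact by construction and tested as such.

**dN/dS.**  Nei–Gojobori (1986) counting: synonymous site fractions per
codon position out of the three possible changes, with changes to stop
codons counted as nonsynonymous (this convention gives S = 0.5, N = 2.5
for the TTT/TTA pair); differences averaged over minimal substitution
paths with equal weights, excluding paths through stop codons when a
stop-free path exists; codon pairs containing a stop are excluded from
the comparison.  Jukes–Cantor correction d = −3/4·ln(1 − 4p/3), flagged
undefined for p ≥ 3/4; ω = dN/dS, undefined when dS = 0.  This is a
deliberate simplification relative to maximum-likelihood codon models:
no transition/transversion bias, no site classes.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes: five
panel genes carrying 44/20/25/36/20 variants (2 coding each, 3 in
*CUL4A*; 11 coding of 145 total), a noncoding mix of 12% 5'UTR / 55%
3'UTR / 33% intronic flank (3'UTR-heavy), 43 of 145 variants rare with
MAF log-uniform on [1e-4, 0.01) and the rest uniform on [0.01, 0.5];
cases 10 + 14 + 11 by endophenotype plus 99 reference individuals.
Genotypes are Hardy–Weinberg draws (dosage ~ Binomial(2, q)) independent
across variants — no linkage disequilibrium, which no burden statistic in
scope uses.  Annotation profiles draw per-category verdicts with
P(possible) = 0.25, P(strong) = 0.10, and a 10% high-impact tail at
0.30/0.50 so that a realistic handful of variants clears the heatmap
threshold; these rates put per-individual score sums near 200–230 points
with a within-group SD around 25, the regime in which the planted
contrast below is detectable at the configured sample sizes.

The planted effect adds an expected score-sum shift δ (default 33.9
points) to one named subgroup (default pre-axial) by *biasing its
carried-variant set toward high-scoring variants*: each non-carried
variant v becomes an extra heterozygous carrier with probability
ε·S(v)/20, with ε solved so the expected extra score is exactly δ.  The
catalogue of variants stays shared across groups — no phantom variants.
Truth tables record every planted parameter (positions, MAFs, verdicts,
scores, δ, ε), and the truth scores are produced by the same rubric code
the pipeline uses, so end-to-end consistency is a tested invariant.

All randomness flows from one master seed through named substreams
(sequences, variants, mafs, annotations, genotypes), so a fixed seed
yields byte-identical files and individual stages can be regenerated
independently.  Gene models are emitted on the plus strand (minus-strand
handling is implemented and tested on hand fixtures); sequences carry a
planted promoter CpG island (400 bp of a CG-rich repeat that passes the
island criteria by construction) and CDSs assembled from random non-stop
codons.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, population stratification, sequencing error and
genotype uncertainty, indels (all variants are SNVs), correlated
predictor verdicts, and mutation-rate heterogeneity along the sequence.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under idealized sampling, not robustness to those real-data features.

## Calibration checks and problem sizes

The test suite verifies, from seeded generator replicates: type-I error
of the case/reference score-sum t-test within 0.05 ± 0.01 at α = 0.05
(2,500 null replicates); ANOVA detection of the planted 33.9-point
pre-axial shift at group sizes 10/14/99 in at least 80% of 250
replicates; recovery of the planted mean difference within 3 standard
errors; MAF recovery at n = 5,000 individuals within 3 binomial SEs for
≥ 99% of variants; and exact agreement of the chi-square and Fisher tests
with closed-form and enumeration oracles on the 2×2 carrier table
[[6,4],[1,13]].  The island detector is checked against an exhaustive
window-enumeration oracle on 2-kb sequences, and the dN/dS site counts
against a per-position enumeration oracle with an independently written
genetic-code table.  Replicate counts were chosen to keep the whole suite
around a minute of statistical simulation while leaving the Monte-Carlo
error well inside the asserted bands.

## Known limitations

- The rubric is a reconstruction with the published ceiling and
  threshold, not the original weight table; conclusions about individual
  variants depend on the weights supplied.
- The dN/dS screen is pairwise and equal-weighted; it is a conservation
  *screen*, not a replacement for ML codon models.
- The Monte-Carlo exact test for sparse location tables conditions on
  margins and is asymptotically, not exactly, equivalent to a full
  network-algorithm exact test.
- Burden comparisons assume independent individuals; no relatedness or
  ancestry adjustment is provided.
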
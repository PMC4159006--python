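# Methods

`underrep` reconstructs, as a reusable pipeline, a comparative-genomics
analysis of underreplicated regions (URs) of the *Drosophila melanogaster*
genome: domains of polytene chromosomes that replicate very late and reach a
lower copy number than the rest of the genome. The analysis asks how gene
conservation, conserved noncoding sequence, noncoding RNAs, protein length
and replication timing differ between these regions and the rest of the
genome. Real dm3 tracks are out of scope; every stage runs on inputs in the
standard text formats (BED, BED12, bedGraph, tab-delimited label tables,
aligned FASTA) or on the package's own synthetic genomes.

## Coordinates and interval algebra

All coordinates are 0-based half-open, the BED convention; 1-based inputs
must be converted at the reader boundary. `RegionSet` merges overlapping and
book-ended intervals at construction, so coverage sums are well defined and
member intervals are disjoint. Strand is carried but ignored by all interval
algebra — every overlap rule in the analysis is strand-agnostic.

The genome is partitioned into exonic, intronic and intergenic bases with
exon precedence: a base inside an exon of *any* isoform of *any* locus is
exonic, even where another isoform or an overlapping gene treats it as
intronic. The source analysis does not state its rule for such bases; exon
precedence is the choice here because it matches how "non-exonic" filters
are used downstream (an element touching any annotated exon is never
noncoding). The three sets tile the declared chromosomes exactly, and the
implementation is tested base-by-base against brute-force classifiers.

## Gene-to-region assignment and matched controls

A gene belongs to the UR set when at least 50% of its genomic length —
from the left-most start to the right-most end over all transcript isoforms
— is covered by UR regions. Coverage sums across regions, so a gene
straddling two regions counts its combined coverage; the rule is "at
least", so exactly half-covered genes are assigned. For protein length and
coding-sequence alignment a single isoform per locus is used: the first in
alphabetical order of isoform name.

For every region an equally sized control set of flanking genes is drawn:
ceil(n/2) nearest genes upstream and floor(n/2) nearest downstream (the
extra gene of an odd count goes upstream; a fixed side keeps the selection
deterministic). Nearness is gene-span-to-region-boundary distance, ties
broken by gene identifier. Eligibility is strict: a candidate overlapping
any UR region by even one base is skipped. When one flank runs out the
deficit is taken from the other; when both run out the pipeline logs the
shortfall rather than failing (the original survey likewise reports slightly
fewer adjacent genes than UR genes).

## Conserved-element sets and enrichment

Highly conserved noncoding elements (HCNEs) are built from four pairwise
conservation tracks by exact base-wise AND (order-invariant), dropping
intersection pieces shorter than 50 bp and pieces overlapping exons by one
base or more. Scored conservation elements (phastCons-style) are filtered at
score > 600 by default; ultraconserved-element (UCE) tracks are taken as
given (their >= 100 bp definition is respected by the generator, not
recomputed from sequence).

Expected element counts are length-proportional: for each annotation
category the genome-wide per-Mb density of elements (assigned to a category
by their midpoint) times the category length inside the regions. Midpoint
membership is the default because it makes the expected counts exactly
length-proportional — the expected mass over inside + outside sums to the
category total, which is asserted in tests. Any-overlap and 50%-coverage
membership rules are available behind a flag. Published tables print
whichever ratio exceeds one under a single "Exp./Obs." heading; this package
always reports both `obs_over_exp` and `exp_over_obs` to avoid the
ambiguity.

Significance uses a two-cell df=1 goodness-of-fit chi-squared
(X² = (O−E)²/E + (O−E)²/(T−E), upper tail) with no continuity correction.
This reconstruction reproduces all six published homolog-depletion p-values
from the printed counts; the published expected counts are rounded to 0.1,
which perturbs the mantissa of p-values of order 1e-35..1e-85, so replay
agreement is asserted on the log10 scale. Two-group contrasts use the
Pearson 2x2 chi-square without Yates correction (the uncorrected statistic,
3.84, matches the printed value; the corrected one does not). No
multiple-testing correction is applied, matching the source analysis; the
run log records how many tests were performed.

Short noncoding RNAs (miRNA, snoRNA, tRNA) are assigned one annotation
category by the majority of their span (exonic > intronic > intergenic on
ties) and counted inside the regions by the 50%-coverage rule; expected
counts scale each class's genome-wide category total by the fraction of
category bases inside the regions. lincRNAs use the 50%-overlap rule and are
summarised by count, mean occupied length inside vs. outside, and the
fraction of region/intergenic bases covered.

## Codon divergence (Pamilo–Bianchi–Li)

Pairwise synonymous and nonsynonymous distances are computed on concatenated
in-frame alignments with the Pamilo–Bianchi–Li (PBL) method. Each codon
position is classified by degeneracy under the universal genetic code:
4-fold if every substitution is synonymous, 0-fold if none is, otherwise
2-fold (the 3-fold isoleucine position counts as 2-fold; substitutions
creating stop codons count as nonsynonymous). With transition proportion
P_i and transversion proportion Q_i per class i in {0, 2, 4}:

    A_i = 1/2 ln(1/(1 − 2P_i − Q_i)) − 1/4 ln(1/(1 − 2Q_i))
    B_i = 1/2 ln(1/(1 − 2Q_i))
    Ks  = (L2·A2 + L4·A4)/(L2 + L4) + B4
    Ka  = A0 + (L0·B0 + L2·B2)/(L0 + L2)
    d4  = A4 + B4

Numerical conventions, each pinned by an oracle test:

* **Gaps/ambiguity:** a codon column containing a gap, N, or stop codon in
  either row of a pair is dropped for that pair only (pairwise deletion),
  so each pair uses its maximal clean column set.
* **Site totals:** L_i is the mean of the two rows' per-class tallies; when
  the two codons disagree about a differing position's class, the difference
  splits 0.5/0.5 between the two classes.
* **Multi-hit codons:** codons differing at 2–3 positions are resolved by
  equal-weight averaging over all shortest substitution pathways that avoid
  stop codons (the Li–Wu–Luo convention); if every pathway passes through a
  stop, the stop constraint is relaxed for that codon pair.
* **Saturation:** a non-positive logarithm argument raises an explicit
  error naming the degeneracy class rather than returning NaN.
* Concatenation is lexicographic by gene id; results are order-invariant
  (asserted by a shuffle test). Genes missing a taxon are dropped with a
  warning. Per-gene distances are never needed: all comparisons run on the
  concatenated contig, which also keeps the estimator far from saturation.

Group comparisons concatenate the UR genes and the adjacent-control genes
into one contig each, compute all pairwise distances across the taxon set
(28 pairs for 8 taxa), and report paired values plus the mean UR/adjacent
ratio per metric, overall and split by human-homolog status.

**Known estimator limitation.** On the universal code a handful of 2-fold
positions (arginine CGA/CGG/AGA/AGG first positions, isoleucine third
positions) have *synonymous transversions*; the degeneracy-class rules
route those neutral events into the nonsynonymous transversion channel.
Against realized substitution counts this inflates Ka when the true
nonsynonymous rate is very low (about +20% at dN/dS = 0.05 in simulation)
while Ka at moderate rates (dN/dS = 0.2) and Ks everywhere are recovered
within about 5%. Rate heterogeneity inside the 2-fold class also leaves Ks
with a small multiple-hit under-correction (2–5% deficit at a 4-fold
divergence of 0.3). Both effects are properties of the method family, are
asserted as such in the test suite, and cancel in UR/adjacent *ratios*,
which is how the method is used here.

## Protein lengths and replication timing

Protein-length summaries report mean, median and quartiles (linear
interpolation, the R type-7 default used by notched box plots; the notch
half-width convention 1.58·IQR/sqrt(n) is provided). Exclusions are by gene
identifier and logged — the published bookkeeping around the single extreme
22,971-aa protein is reproduced from printed (n, mean) pairs by the closed
form (n·mean − outlier)/(n − 1).

Replication timing scores are signed per-probe values (positive = earlier
replication). A locus's score is the unweighted mean over probes overlapping
its span by at least 5 bp ("all probes overlapping" — an overlap-weighted
variant exists behind a flag); loci with no qualifying probe are excluded
from group statistics. The locus span (not merged exon space) is used, which
matches the "probes overlapping every locus" wording. Group contrasts use
the two-sided Wilcoxon/Mann–Whitney rank-sum test: exact enumeration for
tie-free samples up to n = 50, otherwise the tie-corrected normal
approximation with continuity correction (the two branches agree within
|Δp| < 0.01 at n = 30). An option drops a named chromosome first — the X
chromosome for male-derived cell data, where dosage compensation advances
replication.

## The synthetic-genome generator

The generator is first-class, seeded, and deterministic: the same seed and
configuration produce a byte-identical bundle, and every planted truth is
written to a manifest that downstream tests treat as the single source of
truth. The default configuration is a fixed ~1:5-scale rendition of the
study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 8 Mb | scaled from the ~120-Mb fly assembly |
| UR regions | 12, of 150–350 kb (~12% of the genome) | 60 regions / 14.8 Mb / 12% in the survey |
| genes | 2,000; 7% planted inside regions | 13,570 genes, 7% in UR |
| protein lengths | lognormal(5.8, 0.8) aa, min 50 | mean ≈ 460 aa / median ≈ 330 aa as published |
| gene span | CDS × lognormal(0.8, 1.1) expansion | long-tailed so multi-10-kb genes exist |
| homolog labels | human 0.111 in / 0.43 out; mosquito 0.542 / 0.772; virilis 0.93 / 0.97 | the published inside vs. genome-wide fractions |
| testis-specific | 0.35 in / 0.13 out among expression-known (90%) | 35% vs. 13% as published |
| EST support | 0.90 with a distant homolog / 0.83 without | the published 90% / 83% contrast |
| element densities (per Mb, outside; × inside) | UCE 11.9 ×2.0 / 24.1 ×1.3; phastCons600 99.7 ×1.9 / 194.1 ×1.2; HCNE 54.9 ×2.2 / 112.7 ×1.4 (introns / intergenic) | the published densities and enrichment ratios |
| replication scores | conserved mean 1.4, nonconserved 0.5, locus SD 1.5 | the published class means |
| codon model | 8 taxa, star tree, branch lengths 0.03–0.45 subs/4-fold site, kappa 2, dN/dS 0.14 inside / 0.10 outside | a drosophilid-scale divergence spread and the published 1.4× nonsynonymous contrast |

Planted genes lie fully inside or fully outside the regions, so the
manifest's inside list is exact ground truth for the 50% rule (boundary
behaviour is tested separately with hand-built fixtures). HCNE cores (and
short/exonic decoys that exercise the length and exon filters) are placed
mutually non-adjacent and appear in all four tracks — one track exactly,
three with random 0–40 bp margins — while per-track noise elements are kept
clear of everything shared, so the four-way intersection recovers the
planted cores exactly. Replication probes tile the genome at 1-kb steps and
carry the latent score of the locus they overlap most, or baseline noise in
intergenic space.

Codon alignments evolve on a star phylogeny (pairwise-distance estimation
needs no realistic topology, and a star makes the expected pairwise
divergence an analytic sum of two branch lengths). The substitution process
is a per-site nucleotide process with transition bias kappa, nonsynonymous
proposals slowed by a factor omega, and proposals creating stop codons
rejected; rates are normalised so a 4-fold site accumulates exactly the
branch length in expected substitutions. Realized synonymous/nonsynonymous
event counts per branch are logged as ground truth. Alignments are generated
for genes within a configurable flank of the regions (default 300 kb), which
covers every UR gene and every realistic control pick.

What the generator does **not** emulate: real base composition and codon
usage, repeat content, overlapping or nested genes, alternative splicing
beyond a toy two-isoform mode, spatially autocorrelated replication-timing
domains, selection on synonymous sites, and a realistic phylogeny. Passing
tests therefore demonstrate that the pipeline recovers planted statistical
structure through the full file-format round trip — not that the biological
conclusions of the original survey would re-derive from raw data.

## Problem sizes and determinism

Test and acceptance runs use the scales above: full pipeline runs on the
24-Mb default genome (~2,000 genes, ~24,000 probes, ~280 concatenated-gene
alignments per comparison) and divergence recovery on 30,000-codon
alignments — sizes chosen so a complete run finishes in well under a minute
on one core while keeping counting noise a small fraction of every planted
contrast. All randomness flows from a single integer seed through
`numpy.random.default_rng`; pipeline outputs are byte-identical across
reruns with the same seed, which the test suite asserts.
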
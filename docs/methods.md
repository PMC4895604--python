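# Methods

## The problem

RNA editing — deamination of adenosine to inosine by ADAR enzymes (read as
A>G by sequencers) or of cytidine to uridine by APOBEC enzymes (read as
C>T) — is detected from RNA-seq as RNA/DNA differences (RDDs): sites where
the transcriptome consensus disagrees with the reference genome.  The raw
RDD candidate list is dominated by *systematic artefacts*: reproducible
false variants created when short reads are aligned to the wrong member of
a near-identical repeat family, across mis-handled splice junctions, or
onto paralogous sequence.  Because these errors are inherent to the
genome/aligner combination, replication does not remove them.

rddkit classifies raw RDD candidates into true editing versus artefact
with a Random Forest whose training data are compiled *from the input
dataset itself*:

* **positives** — candidates matching a curated known-editing-site
  database (the consensus of DARNED/RADAR-style tables), joined on
  (chrom, pos, strand) with substitution-class compatibility (A>G on +
  / T>C on − for A-to-I; C>T / G>A for C-to-U);
* **negatives** — candidates falling on *error-prone sites* computed by
  the MES procedure: plant random SNVs into simulated reads at the
  dataset's own read length and error profile, align them (or fabricate
  the alignment), call variants, and flag every called-but-not-planted
  site.  Unintended-site identity is position-level: a planted site
  called with the wrong allele is still "intended".

Candidates matching both sources are dropped (ambiguous labels); sites on
a user-supplied test-exclusion list are withheld from training but kept as
prediction targets, so evaluation sites never leak into the classifier.
The remaining candidates are scored by the forest and accepted at a
probability threshold (default 0.5).

## The 15 attributes

Each candidate column is summarised by 15 read-alignment-pattern
attributes in six categories (read depth; allele segregation; mapping
quality; read position; base quality; read strand).  The attribute *names*
follow the samtools/bcftools vocabulary; their formulas are fixed here so
every value is reproducible and testable:

| attribute | definition |
|---|---|
| ReadDepth | observations passing the base-quality filter |
| VAF | alt observations / depth |
| SGB | ln L(hom-ref) − ln L(het) under the 3-hypothesis model below |
| FQ | −10·log10 posterior of the best monomorphic hypothesis (uniform prior), capped at 9999 |
| CallQual | −10·log10 posterior(hom-ref), capped at 9999 |
| MQB, PV3 | z and two-sided p of the tie-corrected, continuity-corrected Mann–Whitney U on alt vs. ref mapping qualities |
| MQ0F | fraction of covering reads with MAPQ 0 |
| MQ | root-mean-square mapping quality |
| VDB | Monte-Carlo probability (M = 1000 draws, per-site seeded) that the variance of alt-base read offsets under uniform placement within each read is ≤ the observed variance |
| RPB | rank-sum z on offset fractions (offset / (read length − 1)) |
| PV4 | rank-sum p on distance to the nearest read end ("tail distance bias") |
| BQB, PV2 | rank-sum z and p on base qualities |
| PV1 | two-sided Fisher exact p on the strand × allele 2×2 table |

The genotype-likelihood block uses per-base error e_i = 10^(−Q_i/10)
(clipped to [1e−10, 0.75]) over ref- and alt-base reads:
L(hom-ref) = ∏_alt(e_i/3)·∏_ref(1−e_i);
L(het) = ∏_all(½(1−e_i) + ½·e_i/3);
L(hom-alt) = ∏_alt(1−e_i)·∏_ref(e_i/3).
Read-position offsets are measured from the sequencing 5′ end (flipped
for reverse-strand alignments).  Degenerate inputs never produce missing
values: an empty comparison group yields the sentinel (z = 0, p = 1), a
single alt observation yields VDB = 1, and p-values are floored at 1e−300
so every p-feature lies in (0, 1].

Two properties of these definitions matter for interpretation.  First,
the rank-sum p is a normal approximation: it agrees with exhaustive
enumeration to within ~0.1 once both groups have ≥4 members, but is coarse
for smaller groups (deviations up to ~0.5 with heavy ties) — the classifier
is agnostic to this, since training and prediction see the same statistic.
Second, Fisher's exact p is conservative by construction (P(p ≤ α) ≤ α for
any discrete exact test), so PV1 is *not* uniform under the null; the test
suite checks it one-sidedly (no anti-conservative excess) and checks the
rank-based p-values and VDB for two-sided KS uniformity at depth 200.

## Candidate calling

Raw RDD candidates are read directly from the pileup: a site qualifies
when depth ≥ 10, a single non-reference base occurs ≥ 2 times (fraction ≥
0, configurable), base quality ≥ 13, after skipping unmapped/secondary/
duplicate reads; columns with two non-reference bases each at ≥ 2 reads
are dropped as multi-allelic and counted.  These thresholds are this
package's stated defaults (the upstream tooling this mirrors does not
print its own) and are exposed on `rddkit call`.

## The synthetic study

Everything is generated programmatically; no external data ships with the
package.  The default scene:

* genome: chr1 = 40 kb carrying one two-copy repeat family (3 kb
  template, 2 % per-copy divergence from the template, hence ~4 % of
  columns differing between copies), chr2 = 20 kb unique;
* transcripts: 2–3-exon gene models tiling both chromosomes on
  alternating strands (exons 300–700 bp, introns 100–400 bp), so repeat
  copies are transcribed;
* reads: 16,000 single-end 100 bp reads sampled uniformly over transcript
  positions (mean exonic depth ≈ 38), i.i.d. per-base error 0.005, base
  qualities encoding the true error model (Q23);
* editing: 200 planted A-to-I sites at editable transcript positions,
  applied per covering read with probability 0.8, with the matching
  known-editing-site database emitted alongside;
* mis-alignment: no aligner is run — reads lying entirely within one
  repeat copy are placed on the homologous copy with probability 0.5
  (MAPQ 20; a fifth of those MAPQ 0), all other reads at their true locus
  (MAPQ 60), exon junctions encoded as N CIGAR operations.  The per-read
  truth table makes every downstream stage exactly scorable.

MES runs 10 trials of 10,000 reads each at planted-SNV rate 1 % (the rate
used in the published artefact simulation), pooled as a union
(recurrence threshold k = 1, the most conservative mask; configurable).
The per-trial report mirrors the published six-column trial table; its
"Caller passed" column applies a stricter QC gate (alt fraction ≥ 0.2,
depth ≥ 10) to the unintended sites and "Filtered" additionally removes
sites inside supplied known-repeat regions.

Validation uses 60 held-out planted edits (positives) and 40 truth-known
artefact columns (negatives), placed on the test-exclusion list so they
are withheld from training yet predicted.  At these conditions the
pipeline reproduces ≥ 90 % of held-out edits and rejects artefacts at
NPV ≥ 75 % — the operating band the approach is designed for.

What the generator does *not* emulate: position- or cycle-dependent error
profiles, indels, PCR duplicates, expression-level variation (uniform
transcript sampling; a per-transcript weight hook exists), paired-end
reads, and real aligner behaviour (mis-placement is injected, not
emergent).  Passing tests therefore demonstrate that the pipeline's
stages are correct and that the classifier separates clean-edit columns
from engineered mis-alignment columns; they do not certify performance on
real libraries, where artefact feature distributions are messier.

Because simulated base qualities are constant per run, the base-quality
rank-sum features (PV2/BQB) are degenerate on synthetic data and the
forest learns nothing from them there; on real data they are active.

## Classifier and attribute ranking

The forest uses 100 trees, unlimited depth, √15 features per split, and a
fixed seed; training errors out if either class is empty (a warning, not
an error, on constant feature columns).  Attribute importance is reported
as information gain IG(attr) = H(class) − Σ_bins p(bin)·H(class|bin) with
10 equal-frequency bins (duplicate quantile edges collapsed), category
score = max over member attributes, ranks per dataset in descending score
with ties as mean ranks, and a mean-rank column across datasets.  Max was
chosen as the category aggregate because it is monotone and scale-free;
mean is available by flag.  No attempt is made to reproduce the published
numeric IG values (the discretization behind them is not printed) — only
the structural properties of the ranking table.

## Numerical conventions

* Coordinates are 1-based and strand-explicit internally; BED (0-based
  half-open) only at the file boundary, with exact conversion.  A 1-based
  site p is inside region (start, end) iff start ≤ p−1 < end.
* All reported percentages round half-up to two decimals (matching the
  printed values the worked examples recompute).
* Every stochastic stage takes an explicit seed; per-site VDB seeds are
  derived by CRC32 from (base seed, chrom, pos) so feature extraction is
  a pure function.
* Likelihoods are computed in log space with logsumexp; phred-scaled
  posteriors cap at 9999.

## Problem sizes

The test suite and the acceptance script run the study at the default
scene above (~16k reads, ~42k pileup columns, ~600 candidates; MES at
10 × 10k reads); the determinism check repeats a reduced study (10k
reads, 3 MES trials) twice and compares outputs byte-for-byte.  These
sizes were chosen so a full verification completes in minutes on one
core while keeping mean depth ≈ 38, comfortably above the depth-30
regime the artefact positive control requires.

## Known limitations

* Single-end reads only; overlapping-mate handling is out of scope.
* The fabricator requires a read to lie wholly inside one repeat copy to
  be eligible for mis-placement; artefacts at copy boundaries are
  under-represented relative to a real aligner.
* MES negatives inherit whatever the variant caller calls: at high trial
  depth a small number of recurrent sequencing-error doubletons enter the
  error-prone mask alongside true mis-alignment columns (they are still
  non-editing, so labels remain correct, but the mask is condition-wide,
  not purely structural).
* Database matching trusts the database: a curated site that is in fact
  an artefact in the user's condition would contribute a mislabeled
  positive.
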
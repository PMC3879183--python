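# Methods

This note documents the models behind `rnaseqbench`, the defaults and the
reasoning for the genuinely open design choices. Nothing here states an
empirical result; the numbers the bench produces come from the test suite
and from `scripts/acceptance.py` at run time.

## Synthetic annotation

The generator builds a genome of five chromosomes carrying (by default) 500
gene loci. Each primary locus gets a gene model: a first exon of 200–400 nt
(kept full-length in every isoform so that all isoforms of a locus share at
least one identical exon interval, as real overlapping isoforms do),
internal exons of 80–350 nt, introns of 100–600 nt, and a target spliced
length drawn log-uniformly between 200 and 12 000 nt — this guarantees both
the very short isoforms near the library's size-selection window and the
multi-kilobase isoforms whose behaviour differs most. Additional isoforms
drop internal exons (probability 0.4 each) and occasionally truncate one
(probability 0.15), producing the staggered exon boundaries that exon-bin
flattening must handle.

Sequence ambiguity — the central difficulty the bench studies — comes from
three deliberately modelled features of vertebrate genomes:

* **Duplicated loci.** 18 paralog pairs and 5 triples whose copies differ
  from their source by exactly `paralog_divergence` substitutions (default
  6, placed at exonic positions: recent duplicates are nearly but not
  perfectly identical, so a minority of reads covers a divergent site and
  is informative). Two further pairs are exactly identical, the limiting
  case in which no method can resolve the copies.
* **Processed-pseudogene-like retrocopies.** 30 single-exon loci, each an
  identical copy of a 210–400 nt interior window of a long (≥1.4 kb) source
  mRNA's spliced sequence. These short nested copies are the classic trap
  for counting heuristics: every read they produce is also compatible with
  the source, and the source contributes more window-compatible reads than
  the copy produces itself.
* **Overlapping gene symbols.** 4% of loci carry two gene symbols; reads
  over such a locus are ambiguous at the symbol level, which the
  discard-ambiguity counting policy resolves by counting nothing.

All coordinates are 0-based half-open internally, 1-based inclusive in GTF
output; transcript coordinates are 1-based.

## Expression designs

The baseline state gives every isoform the same molar fraction. For
differential expression the loci are divided round-robin into 10 chunks;
condition *k* (of 10) up-regulates chunk *k − 1* two-fold and down-regulates
chunk *(k − 1 + 5) mod 10* two-fold, so each condition changes 10% of genes
in each direction, every gene is truly differential in some pairwise
comparisons and null in others, and members of a duplicated family (being
adjacent in locus order) fall in different chunks and are often unequally
expressed — the regime in which multi-read policies separate. Replicates
multiply each isoform fraction by exp(N(0, σ²)) and renormalize; σ is the
biological noise scale (default sdlog 0.25, a moderate between-replicate
scatter; it is a config parameter, not a fitted value). Noise is applied
per isoform; applying it per gene would only tie sibling isoforms together
and was the less general choice.

Switch designs move the entire baseline output of every multi-isoform locus
onto its k-th annotated isoform (k = 1, 2, 3; a locus with fewer isoforms
falls back to its last isoform, recorded in the design log). Locus totals
are conserved exactly before noise, so switch conditions change *what* is
expressed but not *how much* — the situation in which length-naive counts
mistake switching for differential expression.

## Read simulation

Reads are single-end, 101 nt, taken from the 5′ end of retained fragments,
with i.i.d. substitution errors (default 0.1%, no indels; error realism
beyond substitutions is out of scope). Fragment lengths concentrate around
μ_frag = 200 nt with size selection to [150, 300] nt.

* **uniform** — fragment starts are uniform and the expected fragment count
  per molecule is proportional to the number of possible start positions
  max(1, l − μ + 1), so coverage is homogeneous. The sampler draws
  fragments i.i.d. from this generative marginal, i.e. the deeply
  subsampled limit in which each sequenced fragment comes from a distinct
  molecule; per-isoform read counts are then exactly multinomial, which is
  also the premise of the effective-length normalization downstream.
* **coverage_bias** — each molecule is broken iteratively: every piece
  longer than 300 nt is split at a uniform point, for at most 7 rounds,
  then size selection keeps pieces in [150, 300] nt. The bounded number of
  rounds models finite shearing: long molecules still hold mass in
  over-long pieces when selection happens and lose it. This is what makes
  long isoforms underrepresented; with unlimited breakage the expected
  retained yield per nucleotide is asymptotically flat in molecule length
  (for this process the expected piece count from length l is exactly
  l/150 and the retained count l/300 for l > 300), so no length bias would
  remain. Molecules already inside the window convert whole, producing the
  strong overrepresentation peak at the fragment size.
* **tss_polya** — before (homogeneous) fragmentation, each molecule's 5′
  end is truncated by Uniform(0, 100) nt and a poly-A tail of
  Uniform(0, 250) nt is appended. Short isoforms have proportionally more
  reads touching the modified ends, which is why their alignment rates
  drop under this regime.

Every read carries a truth record: generating isoform, locus, and its
interval in unmodified transcript coordinates (absent when the read lies
wholly in the poly-A tail). Truth-based bias analyses use the
effective-length FPKM, `10⁹·c_i/(l_eff,i·N)`, against the nominal FPKM
implied by molar fraction and annotated length, `10⁹·a_i/Σ_j a_j l_j` —
the reference line that is flat when all fractions are equal.

## Alignment

The aligner indexes all spliced transcript sequences with 20-mers and
extends candidate (isoform, diagonal) seeds without gaps (the simulator
emits no indels; gapped alignment would add nothing). Global mode requires
the full read on the transcript with ≤5 mismatches. Local mode finds the
best-scoring contiguous core (match +1, mismatch −3), accepts it if it is
≥20 nt with mismatch density ≤ 5/101, and scores clips at 1 per 4 clipped
bases, so a poly-A tail or an overhang past the transcript end is clipped
rather than fatal. All alignments tying the best score are reported, capped
at 30 per read with a deterministic leftmost-isoform-id tie-break. A read
is *correctly aligned* when at least one alignment lies on an isoform of
its generating locus whose genomic projection overlaps the generating
isoform's span; clipping never voids correctness. The correctness notion is
a locus-projection reading of alignment-coordinate correctness — exact for
genome aligners, adopted here for transcriptome alignment.

## Abundance estimation

Overlap counting projects each read's alignments to loci and applies one of
three policies: `count_all` credits every hit locus, `count_unique` keeps
only reads hitting a single locus that maps to a single gene symbol, and
`fractional` adds 1/m for m distinct hit loci. Gene-symbol tables credit
each symbol of a locus with the locus count.

The isoform model is the standard mixture: a read from isoform i is uniform
over its `l_eff,i = max(1, l_i − μ + 1)` fragment-start positions. EM runs
over compatibility classes (reads grouped by their compatible-isoform
sets); responsibilities are α_i/l_eff,i-proportional over the class, the
M-step renormalizes, and iteration stops when max|Δα| < 1e-8 (up to 5000
iterations — near-identical duplicates create a slow, nearly flat ridge).
Reported are θ (transcript fractions: α/l_eff renormalized), TPM = 10⁶·θ,
expected counts c_i = Σ responsibilities, and FPKM. One subtlety matters
for nested duplicates: an alignment is only *generatively feasible* if a
typical fragment starting there fits the transcript (t_start < l_eff).
Without this filter the class-level likelihood cannot know that the 3′-most
~100 nt of a short retrocopy are alignable but not generatable, and the
MLE systematically misestimates the copy; the filter is the class-level
equivalent of a fully position-aware fragment model. The Gibbs sampler
performs collapsed sweeps over ambiguous read assignments with probability
∝ (n_i,−r + α)/l_eff,i (α = 1, a flat Dirichlet; the posterior mean is
averaged over sweeps after burn-in). The posterior shrinks low-information
isoforms toward the locus mean, so a truly silent isoform sharing all its
sequence with an expressed sibling receives a positive posterior count —
the characteristic behaviour of posterior estimates, traded against their
robustness for genes with unequal near-identical copies.

## Differential expression

All samples have identical library sizes by construction, so no depth
normalization is applied (a total-count scaling hook exists but defaults
off). A single common dispersion φ (NB variance μ + φμ²) is estimated by
maximizing the conditional log-likelihood of within-group counts given
group totals over log φ ∈ [1e-6, 5]; the conditional likelihood is exact
for equal library sizes and genes with zero totals drop out. The exact test
conditions on the two-group total t: group sums are NB with sizes n_A/φ and
n_B/φ, and the p-value accumulates all splits of t whose conditional
probability does not exceed the observed one; φ → 0 reduces to the exact
binomial test. Fractional and posterior counts are rounded to integers
before testing (the test's support is integer; the Poisson-level
approximation this introduces is mild). The log-ratio effect size is
log2((m_A + ½)/(m_B + ½)) ranked by absolute value, and the t-test is a
pooled-variance test on log2(count + ½) with p = 1 when the pooled variance
vanishes.

## Isoform switching

Exon-bin method: each locus is flattened at the sorted union of its exon
boundaries into disjoint bins of constant isoform membership (loci whose
gene symbol spans several genomic loci are excluded and reported — the
flattened annotation cannot represent them). A read increments every bin
its projected primary alignment overlaps; reads hitting several loci are
excluded. Per comparison, bin counts are rescaled per sample by
(geometric-mean gene total / sample gene total) — cancelling plain
expression differences so that only usage changes remain — rounded, and
tested with the exact NB test under a common dispersion estimated over
bins; gene-level aggregation is Bonferroni min-p, chosen for transparency
over power (per-bin p-values are also emitted). This is a bespoke
rescaled-count test realizing the exon-usage paradigm, not a reimplementation
of any specific tool's GLM.

Fraction method: per sample, each multi-isoform locus's isoform-fraction
vector is computed from TPM; the statistic is the square root of the
Jensen–Shannon divergence (natural log) between the two group-mean vectors,
and the p-value comes from group-label permutations — all distinct splits
when there are few (3v3 has 10, flooring attainable p at 0.1, a known power
floor of small designs), otherwise 99 random permutations. Genes with zero
expression in a group, and single-isoform genes, are untested; untested
genes carry p = 1 ("not run" counts as "no switching detected").

## Evaluation

ROC curves sweep the score threshold (p-values oriented as 1 − p, effect
sizes as |log-ratio|); ties contribute diagonal segments and the trapezoid
AUC equals the Mann–Whitney statistic with half credit for ties — verified
against a brute-force pairwise oracle in the tests. Per-gene detectability
builds, for each gene, an AUC over the comparisons it appears in (score =
the gene's score, label = the gene's truth in that comparison); genes
lacking a positive or negative comparison are flagged not assessable. For
this per-gene AUC, tied pairs earn *no* credit: a method that never ranks
any of a gene's truly-changed comparisons above its null ones — notably a
gene with structurally zero counts, whose p-values are all exactly 1 —
scores 0 rather than drifting to 0.5 on ties, and the detectability flag
(AUC ≥ 0.1, configurable) reflects a real inability to see the gene.
FPR analyses report, per significance threshold, the fraction of true-null
genes called significant, separately for count-based and TPM-based scores
in matched switch and no-switch scenarios; TPM-based pseudo-counts are
TPM × assigned reads / 10⁶.

## Default problem sizes

The default experiment uses the desk-scale study conditions: a 500-locus
annotation (~870 isoforms); 100 000 reads per sample for the library-bias
and alignment analyses and for each of the 11 conditions × 3 replicates of
the DE study and the 5 conditions × 3 replicates of the switch study;
200 000 reads per sample for the counting-accuracy analysis (three
differential-condition samples), which needs enough coverage on the short
retrocopies for the policies to separate. Gibbs sampling uses 50 sweeps
with 20 burn-in in the experiment pipeline (200/50 in targeted tests). The
`ExperimentScale.smoke()` preset shrinks everything for quick runs.

## Known limitations

Single-end reads only; no indels, no quality-score realism, no GC bias
(the generator does not model it, so GC-driven effects are invisible
here); no paired-end fragment-length-aware estimation; no discovery of
unannotated isoforms — every method sees the true annotation, which is the
bench's premise, not a claim about de-novo settings. The simulator's
biases are mechanistic idealizations: passing tests show that each analysis
paradigm responds to *these* modelled biases as expected, not that real
libraries contain no others.
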
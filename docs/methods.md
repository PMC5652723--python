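# Methods

This note documents the models implemented in `cistrome_compare`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All intervals are 0-based half-open (BED convention). bedGraph tracks carry
their library size in a `#total_reads=N` header comment because read
identity cannot be recovered from coverage; the generator writes it and the
readers require it (or an explicit argument). Parsers reject rather than
coerce, naming the offending line. Where input files disagree on
chromosome sets, the intersection is used with a warning; fully disjoint
sets are an error.

## Signal comparison

Binned signal is mean per-bp coverage within the bin × 10⁶/total_reads, so
values are linear in coverage and inverse-linear in library size (both are
tested properties). Bins tile each chromosome from 0; a chromosome's last
bin may be shorter and is averaged over its actual width. Only bins
non-zero in at least one profile are kept. PCA treats profiles as
observations and bins as features, centered but not scaled and without a
log transform — the minimal choice when nothing more is specified for
"PCA of normalized signal". Component signs follow the convention that the
first non-zero loading is positive, so scores are reproducible across SVD
implementations.

## Peak comparison

Sharing requires ≥ 1 bp overlap and each peak counts once however many
partners it touches (an interval-sweep implementation is tested against a
quadratic all-pairs oracle). Because call depths can differ by orders of
magnitude between experiments, the heatmap statistic is
max(shared_i, shared_j)/min(n_i, n_j), clipped to 1: nested call sets score
1 rather than being penalized for depth. Genomic assignment is by summit
with precedence promoter > gene body > intergenic; the promoter is TSS
±1 kb and the gene body extends 10 kb downstream (strand-aware) because the
annotation model carries TSSs only, not transcript structures.

## Motif enrichment

The refined peak is peak ∩ [summit−250, summit+250); controls of the same
length abut it immediately upstream and downstream, clipped at chromosome
bounds (densities always use the actually scanned length, so clipping is
unbiased; a peak whose controls vanish entirely is excluded with a
warning). Controls are *not* masked against other refined peaks by default
(`mask_controls=True` changes that) — with sparse peak sets the effect is
nil and masking complicates the length bookkeeping.

The scanner scores log₂-odds against a uniform 0.25 background with a 0.1
pseudocount on the probabilities. Scores are discretized on a 1/1000
lattice and the *exact* null score distribution is built by convolving the
per-position distributions; a window is a hit when its upper-tail
probability is ≤ 1e-4 (the conventional scanning threshold). Both strands
are scanned; windows containing non-ACGT characters are skipped. The hit
sets and p-values are tested against exhaustive enumeration of all words.

Enrichment uses per-occurrence counts (not per-peak indicators):
ES = ((h_peak + 0.5)/bp_peak) / ((h_ctrl + 0.5·bp_ctrl/bp_peak)/bp_ctrl).
The control pseudocount is length-matched so that an all-zero table gives
ES = 1 exactly; with equal lengths this reduces to the plain 0.5/0.5
density ratio. Without the adjustment, zero counts against the 2× longer
controls would force ES = 2 and a sharp decoy motif would appear two-fold
"enriched" purely through the prior. Significance is a Pearson chi-squared
(no continuity correction) on hits vs non-hit scanned positions, peak vs
control; BH q-values run across motifs. A Mann–Whitney utility compares a
motif's log₂ ES between two groups of experiments.

## Target genes

The characteristic profile w(j) is the across-gene average of
strand-oriented binned TSS signal, normalized to sum 1; gene scores are
s_i = Σ_j w(j)·x_i(j), standardized over the gene cohort, with upper-tail
normal p-values and BH calling at q < 0.01. Degenerate dispersion (all
scores equal within float tolerance) is an explicit error, not a silent
epsilon. Genes whose window leaves the chromosome are skipped and counted.

The library default window is ±10 kb at 100-bp bins (the convention of the
probabilistic target-calling literature). The pipeline and the synthetic
studies use ±5 kb: the toy genome spaces TSSs 10 kb apart, so any window
wider than half the spacing would credit a binding site to both its own
gene and its neighbor and no score contrast could separate them. On real
annotations with irregular spacing the ±10 kb default applies; the window
is configurable everywhere.

A hard constraint worth recording: because z-scores are standardized over
the score mixture, a target prevalence of k/n bounds the mean target
z-score by √((n−k)/k), and Σz² = n caps the number of genes that can ever
exceed z = 3 at n/9. FDR-controlled calling at q < 0.01 in a 200-gene
universe is therefore only informative for prevalences well below ~10% —
one reason the generator plants 10 sites per line (see below).

## Pathway enrichment

Pathways with fewer than 40 genes *inside the analysis universe* are
excluded (strict less-than; the filter is on pathway size, not on overlap
size, because filtering on the observed overlap would bias the p-values).
ES is observed/expected overlap; p is the two-sided hypergeometric
probability (sum of point masses ≤ the observed one, tested against full
pmf enumeration). The clustering encoding is sign(ES−1)·(−log₁₀ p) with
*enrichment positive* — the convention every enrichment heatmap uses, kept
consistent here even though one could equally well invert it.

## Activity scores (BASE/iRAS)

Genes are ranked by expression descending with deterministic lexicographic
tie-breaks. T(i) and Non-T(i) are the running fractions of targets and
non-targets among the top i; the raw score is the value of T − Non-T at the
prefix of maximum absolute deviation (sign retained, a signed two-sample
Kolmogorov–Smirnov-type statistic; verified against exhaustive prefix
enumeration on all small instances). Affinity weights are binary.

Normalization is a z-score against n_perm = 1000 random reassignments of
the target labels (the `ratio` alternative divides by the mean absolute
same-sign permutation score). Because label permutation severs any link to
the expression values, a permuted score depends only on where the shuffled
labels land in the rank order — not on the sample — so a single permutation
ensemble per affinity vector serves every sample *exactly*; the ensemble is
seeded by (seed, target-set size), which also makes duplicated affinity
columns score identically. Degenerate nulls (sd = 0) are an error.

## Survival analysis

Sign stratification puts iRAS > 0 in `high`; exact zeros go to `low` with a
logged count (measure-zero for continuous scores). An empty sign group is
an error; an empty quadrant only warns, since the test can proceed on the
remaining groups. Quadrants: 1 = (a>0, b≤0), 2 = (a>0, b>0), 3 = (a≤0,
b≤0), 4 = (a≤0, b>0), with per-group ER-positive fractions reported.
Log-rank and Kaplan–Meier come from lifelines; the Cox model is
statsmodels' proportional-hazards regression with Breslow ties (Efron
behind a flag), with listwise deletion of incomplete rows (logged) and
explicit errors for constant or collinear covariates. Survival times keep
whatever unit the clinical table carries.

## Synthetic data

Defaults: 2 chromosomes × 1 Mb of i.i.d. uniform sequence, 200 genes at
regular 10-kb spacing with alternating strands, 4 cell lines × 2
replicates, 10 binding sites per line, 500 patients. Everything is
deterministic (byte-identical files) under the seed.

Site placement: non-special lines draw 80% of their sites from a common
pool placed promoter-proximally (~80% within ±1 kb of a TSS), the special
line gets a disjoint set placed mostly distal (~75% at 2.2–4.5 kb), each
special peak receiving one planted consensus written into the genome at the
summit. Sites go to interior genes only, so no planted target's TSS window
is truncated at a chromosome end. Ten sites per line keeps target
prevalence at 5% of the universe — the regime where FDR-controlled calling
can separate targets at all (see the z-score bound above) and roughly the
prevalence real cistromes show against genome-wide gene counts.

Coverage is a truncated-normal(1, 0.5) background in 10-bp blocks plus a
triangular bump of height 8 (16× the noise sd) at each summit; replicates
share peaks and differ only in noise. This is deliberately not a read-level
simulator: no fragment-size, mappability or GC bias, no duplicate reads,
and the background is homogeneous. Passing tests therefore demonstrate the
*statistical machinery* recovers planted structure, not robustness to real
ChIP-seq artifacts.

The cohort: ER status is Bernoulli(0.5); the special-line signature
activity is N(+1, 0.5) in ER+ and N(−1, 0.5) in ER− samples, the
other-lines activity the mirror image; expression is N(0,1) plus
(effect = 1) × activity on the signature's genes; survival is exponential
with log-hazard 0.7 per unit of the other-lines activity (baseline 0.01
events/month) under independent uniform censoring on [0, 300] months. Note
the hazard depends *only* on the other-lines activity: quadrant groups 1
(special-high/other-low) and 3 (both-low) are equal in expectation, but
group 3 is nearly empty under the anti-correlated activities, so group 1
carries the "ER-rich and best outcome" pattern among populated groups.

## Problem sizes

The default pipeline (2 Mb genome, 8 tracks, 200 genes, 500 patients,
1000 permutations) completes in well under a minute; the recovery studies
use 20 fresh simulations for target calling, n = 500 for activity
correlation, and n = 1000 patients for Cox coefficient recovery. These
sizes were chosen so the whole suite exercises every stage at statistically
meaningful power while staying desk-scale.

## Known limitations

- The coverage model cannot test peak *calling* (peaks are taken as given,
  matching the pipeline's contract with an upstream caller).
- The scanner's uniform background is appropriate for the uniform toy
  genome; real-genome scanning would want a composition-matched background.
- Binary affinity vectors discard binding strength; continuous weighting is
  out of scope.
- The Cox model assumes proportional hazards and offers no diagnostics;
  competing risks and time-varying covariates are out of scope.
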
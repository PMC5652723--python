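# cistrome-compare

A library for comparing a transcription factor's cistrome — its
genome-wide set of binding sites — across cell lines at four levels (raw
signal, peaks, motifs, target genes), and for propagating the resulting
target-gene sets into tumor expression cohorts to score per-patient
regulatory activity and test its association with survival.

The motivating biology: the same transcription factor can bind almost
disjoint site sets in different cell contexts when a co-factor (for example
a hormone receptor) recruits it to its own motifs. The pipeline quantifies
that divergence layer by layer and asks whether the divergent target
programs carry opposite prognostic information in patients.

## What it computes

**Signal level.** Genome coverage is binned (100 bp default) as mean per-bp
coverage × 10⁶ / total reads; bins non-zero in at least one profile enter a
PCA with profiles as observations (centered, unscaled).

**Peak level.** Peaks are *shared* given ≥ 1 bp overlap; the overlap
coefficient is max(shared_i, shared_j)/min(n_i, n_j). Summits are assigned
promoter (±1 kb of a TSS) > gene body > intergenic, and TSS ±3 kb
meta-profiles are computed with strand mirroring.

**Motif level.** Each peak is refined to its summit ±250 bp window; two
controls of equal length abut the refined peak up- and downstream. A PWM
scanner with *exact* null p-values (dynamic programming over the
discretized log-odds score distribution, uniform background) counts
occurrences; the enrichment score is the pseudocounted hit-density ratio
peak/control, tested with a 2×2 chi-squared on position-level counts and
corrected by Benjamini–Hochberg.

**Target level.** A TIP-style model scores each gene:
s_i = Σ_j w(j)·x_i(j), where w is the normalized average TSS-centered
binding profile and x_i the gene's strand-oriented binned signal;
z = (s − mean)/sd over genes, upper-tail normal p, BH, targets at q < 0.01.
Per-cell-line target sets merge into binary binding-affinity vectors
g_j ∈ {0,1}ⁿ, and target-set sharing is tested hypergeometrically.

**Pathway level.** Two-sided hypergeometric enrichment of target sets in
pathways (≥ 40 genes in the universe), encoded as sign(ES−1)·(−log₁₀ p).

**Activity level (BASE/iRAS).** For a sample with expression
S = {s_1…s_n}, genes are ranked descending and two running CDFs are
tracked: T(i) over targets, Non-T(i) over non-targets. The raw score is the
signed maximum of T(i) − Non-T(i); normalizing against 1000 random
permutations of the target labels gives the individual Regulatory Activity
Score (iRAS) in standard-score units.

**Survival level.** Patients split by iRAS sign (high: > 0) or into four
quadrants of two iRAS columns; Kaplan–Meier curves with log-rank tests, and
a multivariate Cox model (Breslow ties) checks independence from clinical
covariates.

A synthetic-data module generates the full study design with known ground
truth: a toy genome, cell lines sharing promoter-proximal sites plus one
line with distal, motif-bearing sites, and a patient cohort with two
opposite-signed, receptor-linked signature activities, one driving hazard.

## Worked example

```
python examples/06_activity_and_survival.py
```

prints (seed 7, 500 patients):

```
iRAS_MCF7_like: mean in ER+ +1.75, ER- -1.85
iRAS_line2: mean in ER+ -1.70, ER- +1.74
sign stratification by iRAS_line2: log-rank p = 9e-26
quadrant sizes: {'4': 231, '1': 224, '3': 25, '2': 20} ER+ fraction per group: {'4': 0.01, '1': 1.0, '3': 0.52, '2': 0.65}
Cox log-HR per covariate: {'iras_other': 0.161, 'er': -0.748, 'age': 0.004}
```

The two signatures score with opposite signs in ER-positive versus
ER-negative patients; stratifying by the proliferation-like activity
separates survival strongly; quadrant group 1 (special-line activity high,
other low) is almost entirely ER-positive; and the other-line activity
remains positively associated with hazard after adjusting for ER status and
age. The other `examples/*.py` scripts walk through each analysis level the
same way; `cistrome-compare simulate` and `cistrome-compare run-all` expose
the generator and the end-to-end pipeline from the shell.

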
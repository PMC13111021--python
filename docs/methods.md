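# Methods

This note documents the models, conventions and design choices behind
`tcrdyn`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Clonotype model

A clonotype is the triple (CDR3 nucleotide sequence, V gene, J gene) with a
summed read count. Gene calls are reduced to gene level: allele suffixes
(`*NN`) are stripped and only the first gene of a multi-assignment call is
kept, because convergence is defined on V *gene* segments and allele-level
resolution is unreliable in amplicon data. Junctions are translated in
frame 1 under the standard genetic code; a junction is productive iff its
length is divisible by three and the translation is stop-free. Unproductive
junctions are removed before any metric is computed — the amino-acid-level
convergence definition presupposes translatable sequences — but their read
mass is retained in a discard tally so that parsing stays lossless
(`depth + discarded = input reads`). A `junction_aa` column in input files
is ignored and recomputed by translation, guaranteeing internal
consistency between the nucleotide and amino-acid levels.

## Convergence

A convergent group is an equivalence class under exact (V gene, CDR3
amino-acid) identity containing at least two *distinct* nucleotide
sequences. The J gene is deliberately excluded from the convergence key
(two rearrangements differing only in J but sharing a nucleotide sequence
are not convergent — the nucleotide sequences are not distinct). No fuzzy
amino-acid matching is attempted. Convergence frequency is the summed read
count of all groups divided by sample depth, so it is a proportion in
[0, 1] and equals 0 whenever every amino-acid sequence is unique within
its V gene. The implementation is hash-grouping by (V, aa); the test suite
checks it against an all-pairs union-find oracle on random repertoires.

## Rarefaction

Samples are subsampled to a common depth without replacement; the drawn
counts follow the multivariate hypergeometric distribution over clonotype
counts, which is exactly the distribution of shuffling the read pool and
keeping the first `depth` reads (verified against an enumeration oracle by
chi-square goodness of fit). The default depth policy is the minimum depth
across samples passing QC, with a fixed-depth override; samples below a
fixed target are excluded with a logged reason. One draw per sample per
analysis under a single recorded seed; replicate-averaged rarefaction is
intentionally not implemented. All per-sample metrics, including
convergence, are computed on the rarefied sample.

## Diversity metrics

Shannon diversity uses the natural logarithm; the base cancels in Pielou's
evenness $J = H/\ln S$. Evenness is reported missing (NaN) for single-clone
repertoires rather than 0, since $J$ is undefined at $S = 1$. Percent
decline is kept at full precision internally and rounded to integer
percent only for display.

## Multivariate structure

The clone-frequency matrix keys clonotypes at the (V gene, CDR3 aa) level
— matching the antigen-recognition framing of convergence — with a
nucleotide-level option. Columns are truncated to the top 500 classes by
mean frequency (ties broken lexicographically) to bound dimensionality.
PCA centres columns but applies no variance scaling or log transform; the
sign of each component is fixed by making its largest-magnitude loading
positive, so scores are reproducible across linear-algebra backends. Group
comparison on a component uses the Wilcoxon rank-sum test on scores;
per-group dispersion (range and SD) describes scatter along a component.

## Inference

All tests are two-sided. The Wilcoxon rank-sum test uses the exact null
distribution when there are no ties and the smaller group has at most 10
observations (the motivating cohort has groups of 4 and 11), otherwise the
normal approximation with tie and continuity corrections. The Spearman
trend statistic is Pearson's correlation on mid-ranks; its p-value is an
exact full permutation when the number of distinct arrangements of the
(heavily tied) time-point vector is small, otherwise the t approximation.
A Shapiro–Wilk gate at 0.05 chooses between the parametric (Pearson) and
nonparametric (Spearman/Wilcoxon) families for continuous summaries.

Benjamini–Hochberg correction is applied over a *registered* family of
primary tests — by default the three the pipeline runs: the convergence
trend over time in the disease-control group (time points coded 1/2/3,
only T1/T2 enter pooled analyses), the group comparison of T2−T1
unique-clone deltas, and the group comparison of PC1 scores. Descriptive
p-values outside the registry are reported uncorrected. Significance
convention: p < 0.05 and q < 0.05.

Survival uses the Kaplan–Meier product-limit estimator with right
censoring and the two-group log-rank test (1 df); with zero events the
test is flagged not evaluable rather than given an arbitrary p. Patients
whose response is not evaluable (NE) have no group and are excluded from
group-stratified analyses and from the survival comparison.

Attrition accounting treats the sample track (enrolled → T1 → T2 → T3) as
cumulative, while the overall-survival population branches from the
baseline-evaluable count minus only the exclusions recorded at the OS
stage, because survival follow-up is independent of blood-sample
availability.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, at desk
scale: by default 11 disease-control (DCG) and 4 progressive-disease (PD)
patients, ~2,800 baseline clones per patient (8% lognormal-ish jitter),
50,000 reads per sample, and power-law rank-abundances
$p_r \propto r^{-1}$. Real repertoires run to >10⁶ reads; depth is a
configuration knob and all metrics are computed after rarefaction to a
common depth, so pipeline-correctness conclusions transfer, while
data-derived values from any real cohort are explicitly not reproduced.

Key mechanisms:

- **Codon degeneracy.** Convergent classes are created by splitting a
  clone's abundance across 2–4 distinct synonymous encodings of its CDR3
  (drawn without replacement from the exact encoding space of the standard
  genetic code). Injection proceeds greedily over clones whose mass fits
  the remaining budget, with per-class mass capped at ~1/6 of the budget so
  later *reductions* (de-converging classes to emulate a declining trend)
  have fine granularity. Every generated junction is productive by
  construction and every nucleotide sequence translates to its intended
  amino-acid sequence.
- **Group convergence levels.** Default injections 0.0040 (DCG) and
  0.0023 (PD) at T1. At T2 the DCG target is scaled by 0.6, producing the
  declining convergence trend in disease control; PD stays at its level.
  An optional PD scenario (`t3_for_pd`) raises PD convergence threefold at
  T2 and drops it at T3, emulating transient treatment-induced activation
  followed by attrition.
- **Clone retention.** T2 repertoires arise by Bernoulli retention of each
  nucleotide clonotype at the group rate (defaults 0.84 DCG, 0.59 PD) with
  renormalised abundances, so the expected unique-clone decline is the
  retention complement (16% / 41%). Fresh-clone influx at T2 is a knob
  (`novel_clone_fraction`) defaulting to 0 so that the observed decline
  tracks retention; read depth is held fixed by the multinomial draw
  regardless. Observed declines sit slightly below the complements because
  tail clones escape detection more often at T1 (when abundances are
  spread thinner) than at T2.
- **Repertoire architecture.** DCG patients share a pool of 25 dominant
  public clonotypes carrying 15% of read mass (with mild per-patient
  jitter), giving the group its compact, stable multivariate structure; PD
  patients each receive an idiosyncratic dominant private clone with mass
  drawn uniformly from [0.05, 0.35], producing wide per-patient scatter.
  These masses are realism choices for the dominance structure, made once
  and documented here; the PCA dispersion contrast (PD wider than DCG on
  PC2) is an emergent consequence checked across seeds, not fitted.
- **Survival.** Exponential death times with default hazards 4×10⁻⁴/day
  (DCG) and 3.5×10⁻³/day (PD; median ≈ 198 days), administratively
  censored at day 420 — mirroring a cohort whose disease-control arm has
  immature survival data within the observation window.
- **Responses.** Within DCG, PR is assigned to a fixed fraction (4/11 by
  default) and SD to the rest, deterministically.

What the generator does **not** emulate: V(D)J recombination statistics,
germline sequence content, thymic selection or HLA restriction, sequencing
error, PCR amplification bias, or batch effects. Passing tests therefore
demonstrate correctness of the computations and recoverability of the
generator's own parameters, not biological validity on real sequencing
data.

## Numerical conventions and degenerate inputs

Frequency vectors must be strictly positive and sum to 1 within 1e-9.
Constant vectors are rejected where a statistic is undefined (Shapiro–Wilk
W, Spearman rho, PCA on a constant matrix). Deterministic tie-breaks
throughout: clonotype output order is descending count then lexicographic
key; frequency-matrix column order is descending mean frequency then
lexicographic. A single integer seed drives every stochastic step
(rarefaction draws, simulation) through one `numpy` generator, and re-runs
with the same configuration are bit-identical.

## Problem sizes used in the checks

The automated checks run at desk scale chosen for a single CPU: oracle
equivalences on repertoires of ≤ 200 clonotypes (100 random samples), exact
test enumerations at n ≤ 8 per group, and parameter recovery on 20 default
cohorts (15 patients × 2 time points × 50,000 reads each). These sizes are
the package's own verification conditions; all thresholds (±5 percentage
points on recovered declines, ±0.02 on realized convergence, ≥80% power and
dispersion-ordering rates, ≥90% survival-ordering rate) were fixed with the
generator defaults before use.

## Known limitations

- Convergence detection is exact-match only; sequencing-error-induced
  pseudo-variants in real data would inflate convergence and should be
  handled upstream (denoising) or by count thresholds, neither of which is
  implemented here.
- The rarefaction depth policy cannot recover per-sample QC decisions made
  by the original instrument software; it only reproduces the
  "minimum across passing samples" convention.
- The exact Spearman permutation p is limited to small n (≤ 10, or any n
  whose tied arrangement count stays under 10⁵); beyond that the t
  approximation is used.
- PCA on frequency matrices with more features than samples is a
  low-rank projection; score coordinates depend on the top-M truncation
  (default 500 columns), which is a documented choice, not an inference.
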
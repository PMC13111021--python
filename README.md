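# tcrdyn

Longitudinal T-cell receptor beta-chain (TCRβ) repertoire dynamics for
treatment cohorts: clonotype collapsing, convergent-rearrangement
detection, rarefaction, diversity metrics, clone-frequency PCA, rank-based
group inference with false-discovery-rate control, and Kaplan–Meier
survival stratification — plus a synthetic cohort generator with known
ground truth so every stage is testable without sequencing data.

## The scientific problem

Cytotoxic chemotherapy perturbs the circulating T-cell compartment, and the
way a patient's TCRβ repertoire reorganises under treatment carries
prognostic information: patients who achieve disease control tend to keep a
broader repertoire (smaller loss of unique clones between baseline and
post-treatment sampling) and a more *convergent* one, whereas progressive
disease is marked by stronger clonal attrition and heterogeneous,
idiosyncratic repertoire structure. `tcrdyn` implements the analysis layer
that quantifies these dynamics from per-sample clonotype tables (AIRR
Rearrangement TSV dialect) and a cohort manifest.

The metrics, in standard notation with clonotype frequencies
$p_1,\dots,p_S$ at a common rarefaction depth:

- **Clonotype identity** — a unique CDR3 nucleotide sequence combined with
  V and J gene usage (gene-level, alleles stripped); read counts of
  identical keys are summed and unproductive junctions are discarded.
- **Shannon diversity** $H = -\sum_i p_i \ln p_i$ (nats) and **Pielou
  evenness** $J = H / \ln S$ (undefined at $S=1$).
- **TCR convergence frequency** — the cumulative read fraction of
  clonotypes sharing an identical CDR3 amino-acid sequence and V gene but
  encoded by two or more distinct nucleotide sequences; a surrogate for
  antigen-driven convergent selection. Dimensionless, in $[0,1]$.
- **Unique clone count** and its T1→T2 **percent decline**
  $(U_{\text{pre}}-U_{\text{post}})/U_{\text{pre}} \times 100$.
- **Rarefaction** — exact multivariate-hypergeometric subsampling of reads
  (without replacement) to the minimum depth across samples.
- **Clone-frequency PCA** — samples embedded by (V gene, CDR3 aa) class
  frequencies, column-centred, deterministic sign convention.
- **Inference** — two-sided Wilcoxon rank-sum (exact for small groups),
  Spearman trend with exact permutation p for small n, a Shapiro–Wilk
  normality gate, Benjamini–Hochberg correction over a registered family
  of primary tests (three by default), and Kaplan–Meier curves with the
  two-group log-rank test.

## Worked example

Simulate a small cohort (5 disease-control and 3 progressive-disease
patients, 250 clones and 5,000 reads per sample) and run the full
analysis:

```bash
$ tcrdyn simulate --out demo/cohort --seed 7 --n-dcg 5 --n-pd 3 --depth 5000 --clones 250
wrote 16 samples; manifest: demo/cohort/manifest.csv

$ tcrdyn run --manifest demo/cohort/manifest.csv --out demo/report --seed 7
rarefaction depth: 5000
                          name  statistic        p        q  evaluable note  n_n  n_x  n_y
spearman_convergence_trend_dcg  -0.707107 0.055556 0.083333       True      10.0  NaN  NaN
         wilcoxon_delta_clones  15.000000 0.035714 0.083333       True       NaN  5.0  3.0
                  wilcoxon_pc1  17.000000 0.180569 0.180569       True       NaN 10.0  6.0
log-rank p = 0.0732
```

Reading the output: convergence trends downward over time in the
disease-control group (Spearman ρ = −0.71), the loss of unique clones
differs between groups (raw Wilcoxon p = 0.036 on the T2−T1 clone-count
deltas), and PC1 scores do not separate the groups at this tiny cohort
size. The `q` column is the BH-adjusted value over the three-test family;
at this scale only the raw delta-clone p crosses 0.05. The report directory
holds `metrics.tsv` (one row per sample: depth, unique clones, Shannon,
evenness, convergence), `deltas.tsv`, `tests.tsv`, PCA scores and loadings,
Kaplan–Meier curves, attrition accounting, and a JSON-lines run log with
the seed and every exclusion.

The same steps are available as library calls
(`tcrdyn.simulate_longitudinal_cohort`, `tcrdyn.run_pipeline`, and the
per-metric functions) for scripted use.

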
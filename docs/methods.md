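# Methods

## The analysis in one paragraph

Anaplastic thyroid carcinoma (ATC) lacks selective positive markers; the
pipeline looks for genes that are *de novo* expressed — effectively silent
in every other thyroid tissue class but strongly and consistently induced
in ATC — and then quantifies how well the protein product of such a gene
separates ATC from other thyroid carcinomas in immunohistochemistry (IHC)
cohorts. Discovery runs on a gene × sample count matrix with class labels
in {ATC, PTC, FTC, PDTC, NT}; the comparison group "noATC" pools every
non-ATC sample. Validation runs on per-sample staining records or pooled
cohort counts.

## Normalization and FPM

Between-sample normalization uses the trimmed mean of M-values (TMM).
For sample *s* against a reference *r* (the column whose upper quartile of
scaled counts is closest to the mean upper quartile), genes expressed in
both columns contribute a log-ratio M<sub>g</sub> = log₂((y<sub>gs</sub>/N<sub>s</sub>)/(y<sub>gr</sub>/N<sub>r</sub>)),
an abundance A<sub>g</sub>, and a precision weight from the delta-method
asymptotic variance (N−y)/(Ny) summed over the two samples. M is trimmed
30% on each side, A 5% (rank-based, ties averaged); the factor is the
weighted mean of surviving M, exponentiated, and all factors are rescaled
to geometric mean 1. An all-zero column is an error naming the sample; if
trimming leaves no genes the factor falls back to 1 with a logged warning.

FPM (fragments per million) is defined as counts per million of
*effective* library size (raw column total × TMM factor); with unit
factors every column sums to 10⁶. FPM is the unit of the screen's
thresholds.

## Dispersion and the exact test

Counts are modelled NB with Var = μ + φμ². A single common dispersion φ
is estimated by Cox–Reid adjusted profile likelihood: counts are rescaled
(mean-preserving) to a common effective library size, group means are
profiled out, and the pooled log-likelihood minus half the log Fisher
information of each profiled mean is maximized over φ ∈ [10⁻⁶, 5] on the
log scale. The adjustment matters: plain profile ML underestimates φ by a
factor ≈ (n−1)/n per group; parameter-recovery tests (φ = 0.2, 2000 genes)
confirm the adjusted estimator is unbiased to within a few percent.

The ATC-vs-noATC test is a conditional exact test. After library-size
equalization (scaled counts rounded to the nearest integer), the group-A
total given the overall total *t* is free of the gene's mean: negative
hypergeometric under NB (group totals are NB sharing one success
probability), binomial in the Poisson limit. The two-sided p-value sums
the conditional probabilities of all splits no more likely than the
observed one (tie-inclusive), capped at 1. This convention matches the
exhaustive-enumeration oracle in the test suite to 10⁻¹⁰ and holds its
size: over 10⁴ simulated null genes at φ = 0.1 the rejection rate at
α = 0.05 stays within [0.04, 0.06].

Log₂ fold changes add a prior offset of 0.125 counts per group at the
common library size (expressed in FPM units) so that de novo genes — whose
noATC mean is ~0 — get finite, stable estimates. FDR is Benjamini–Hochberg
(statsmodels). The QC embedding is a full-SVD PCA of samples on
log₂(FPM + 1) with genes centered.

## The de novo marker screen

A gene is a candidate when, simultaneously, (i) mean FPM in noATC < 1
(strict), (ii) fold change in ATC vs noATC > 50 (strict, computed on the
same prior-offset ratio as the DE log₂FC — a raw ratio would divide by ~0
for exactly the genes the screen targets), and (iii) FDR ≤ 0.01
(non-strict). Candidates are ranked by increasing RSD of FPM across ATC
samples, using the n−1 standard deviation (ATC cohorts are small; the
convention must be fixed for reproducibility). Genes with zero ATC mean
have undefined RSD and are excluded before ranking. Ties break by
ascending FDR, then gene id. The top-K (default 20) are annotated against
a user-supplied cancer-testis gene list. Whether the FDR threshold is part
of the screen or only of the volcano display is ambiguous in practice; it
is included by default and exposed as a parameter.

## Preranked GSEA

Genes are ranked by descending fold change (ties by gene id). The
enrichment score is the signed extremum of the weighted KS running sum:
hits add |score|^p / Σ_hits |score|^p (p = 1 by default), misses subtract
1/(N − N_hits); the sum starts and ends at zero. Because the input is a
preranked list, the null is gene-set permutation: ES of random same-size
sets (≥ 100 permutations, default 1000, seeded). NES divides ES by the
mean |null ES| of matching sign; the nominal p is the matching-sign null
tail with add-one smoothing. q-values follow the standard pooled-null FDR:
for each observed NES, the fraction of pooled sign-normalized null NES at
least as extreme over the fraction of observed NES at least as extreme,
clipped to [0, 1], then each set takes the minimum estimated FDR over all
cutoffs that include it. Sets are restricted to 5–500 members after
intersection with the universe; a set covering the whole universe (miss
decrement undefined) or missing from it is rejected.

## IHC diagnostics

Histoscore H = Σᵢ i·pctᵢ over intensities 0 (negative) to 3 (intense);
bins: absent (0), low (1–100], intermediate (101–200], strong (201–300].
Positivity defaults to *any detectable staining* (H > 0) — a low-score
sample still counts as positive — with an optional numeric threshold.

Contingency tables pool cohorts: TP/FN from ATC, FP/TN from the other
carcinomas (PDTC + PTC + FTC); normal tissue is excluded by default
because the diagnostic question is ATC vs other thyroid *carcinomas*.
The bundled cohort-count table (three cohorts: an RNA-seq test cohort and
two tissue microarrays; markers IGF2BP1, MAGEA3, MYC) uses 44 TMA-II PTC
samples, i.e. 205 non-ATC carcinomas, the denominator consistent with the
published odds ratios.

- DOR = (TP·TN)/(FN·FP); if any cell is zero, 0.5 is added to *all four*
  cells (Haldane–Anscombe) for both the point estimate and the CI. The CI
  is the log method: exp(ln DOR ± z·√(1/TP + 1/FN + 1/FP + 1/TN)).
- Sensitivity/specificity CIs: Wilson score (statsmodels).
- PPV/NPV at a prevalence π (default: sample prevalence, where they reduce
  to TP/(TP+FP) and TN/(TN+FN)); CIs by the standard-logit (Mercaldo)
  method with variances (1−se)/(se·n₁) + sp/((1−sp)·n₀) for PPV and
  se/((1−se)·n₁) + (1−sp)/(sp·n₀) for NPV, back-transformed. Degenerate
  se or sp (0 or 1) triggers the 0.5 correction for the CI and is flagged.

On the bundled counts these closed forms give DOR 612 (CI lower 74.6) for
IGF2BP1, 411 after correction (CI lower 23.8) for MAGEA3, and 30.7 with
PPV 61.9% (CI 49.3–73.1%) for MYC — recomputed, not stored, by
`scripts/acceptance.py` and the test suite.

## The synthetic cohort

The generator emulates the discovery cohort: classes ATC 10, PTC 6, FTC 6,
NT 6 by default; per-gene baseline means log-normal (ln-mean 6.0, ln-sd
1.5, i.e. a median of ~400 expected counts); per-gene dispersions
Gamma(shape 2, scale 0.05), mean φ = 0.1, typical of bulk tissue cohorts;
library-size factors log-uniform in (0.5, 2.0) so TMM is exercised
nontrivially. Spiked markers get an expected noATC level of 0.2 FPM
("near-zero") and a 200-fold ATC induction; their ATC dispersion is set so
the expression CV matches a target RSD of 0.2. Decoys split evenly between
(i) genes that pass the expression filters but are overdispersed in ATC
(φ = 1.5, RSD ≈ 1.2 — they must lose the ranking) and (ii) genes at 5 FPM
in noATC (they must fail the de novo filter). FPM targets are converted to
count units via the background library total, so the spike thresholds hold
by construction in expectation and, at these sizes, empirically.

IHC cohorts draw positivity per (class, marker) as Bernoulli; positive
samples draw intensity percentages from a Dirichlet over intensities 0–3
(concentration (0.5, 1.5, 2.0, 1.5)) scaled to 100 — almost surely H > 0 —
and negative samples are 100% intensity 0.

What the generator does *not* emulate: batch effects, paired tumor/normal
structure, gene–gene correlation, length-dependent counting, tagwise
dispersion trends, or inter-rater scoring noise in IHC. Passing
recovery tests therefore show the screen's statistical machinery is
correct under its own model, not that real cohorts of this size always
yield 20/20 recovery.

## Problem sizes and numerical choices

The default simulation (2000 genes, 28 samples) keeps a full
simulate → DE → screen → GSEA run at a few seconds; the calibration
simulation uses 10⁴ genes at a ln-mean of 3.5 (~30 counts/sample) so the
exact-test enumeration over totals stays fast while leaving the discrete
conditional distribution near-continuous. The exact test rounds
library-equalized counts to integers; with equal library sizes it is exact
enumeration. The dispersion optimizer works on log φ with a bounded
scalar search (xatol 10⁻⁶) and snaps to the lower bound when the
likelihood is non-increasing there. Ranking ties and permutation draws are
all seeded or deterministic, so identical configurations reproduce
byte-identical outputs.

## Known limitations

- The DE stage estimates one common dispersion; tagwise empirical-Bayes
  shrinkage and GLM/quasi-likelihood testing are out of scope, so genes
  with atypical dispersion are tested at the pooled φ.
- The screen's published top-20 table for the motivating study can only be
  reproduced from the original deposited cohort data; the package
  validates the screen by parameter recovery on synthetic cohorts instead.
- GSEA uses gene-set permutation (the only option for a preranked list);
  its q-values are not comparable to phenotype-permutation GSEA.
- PPV/NPV are prevalence-dependent; values at sample prevalence from
  pooled cohorts inherit the cohorts' case mix.
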
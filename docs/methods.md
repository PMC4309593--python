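# Methods

## Generative model for synthetic panels

Background haplotypes are drawn from a first-order Markov chain over SNPs
with specified marginal ALT frequencies and a tunable adjacent-SNP allele
correlation `rho` (`background_ld_decay`); correlation decays as `rho^d`
with SNP distance. This is deliberately the simplest model producing local
LD — no coalescent or demographic realism is attempted, so long-range LD,
allele-frequency spectra and recombination hotspots of real data are not
reproduced. Conditional probabilities are clipped to [0, 1], so for extreme
frequency combinations the realised correlation can fall slightly below
`rho`.

The founder haplotype is a fixed allele pattern: the minor allele at a
small set of signature SNPs (default 3, spread over the window interior)
and the major allele elsewhere. Each haplotype is a founder copy with
probability `founder_hap_freq`; each founder copy carries the focal
mutation with probability `sensitivity_t` — and non-founder haplotypes
never carry it, enforcing perfect specificity by construction. Optional
edge erosion reverts founder alleles to background in geometric runs from
both window ends, mimicking recombination decay of the ancestral segment.
All randomness flows from one seed through spawned generator streams, so
panels are bit-identical under a fixed seed.

Consequences for what the tests show: passing tests demonstrate that the
algorithms are correct *under the single-origin, perfectly specific
founder model* and robust to the noise sources the generator includes
(imperfect sensitivity, background LD, edge erosion, enriched sampling).
They cannot certify behaviour under recurrent mutation, genotyping error,
or phasing error, which the generator does not model.

### Engineered reference fixture

`enriched_reference_fixture` builds a panel with *exact* marginals rather
than random draws: 2,370 haplotypes, 24 mutation-bearing founder copies
plus a configurable number of mutation-free founder copies, each on a
distinct individual. The three signature minor alleles are individually
common in the background (roughly 3–4% of haplotypes each) but never
co-occur there, and the pairwise-overlap background rows differ from the
founder pattern only at the missing signature SNP. This makes the
founder-isolating split sequence unique, so the greedy tree must use all
three signature SNPs — mirroring a reference panel in which no single SNP
tags a rare founder mutation but a short haplotype does.
`add_secondary_signature` overlays a weaker 4-SNP signature with the same
overlap discipline, minus a few "eroded" carrier copies, to exercise the
iterative masking analysis.

### Phenotypes

Binary phenotypes follow a logistic model with a baseline prevalence and
an odds ratio per dosage unit; time-to-onset phenotypes follow a Weibull
proportional-hazards model (shape 1 = exponential) with normal censoring
ages, using **age as the time scale** throughout. Cross-phenotype case
overlap beyond what the shared dosage induces is generated by a shared
normal frailty added to every phenotype's linear predictor
(`shared_frailty_sd`); a direct "overlap rate" is not a parameter of any
coherent generative model, but the frailty SD tunes overlap monotonically.

## SNP quality control

SNPs are removed when the overall call rate is below 0.95 or the exact
Hardy-Weinberg p-value is below a Bonferroni-corrected threshold (0.05
divided by the number of SNPs tested, kept as the exact quotient). Removal
uses strict inequalities; a SNP at exactly the call-rate threshold is
retained. The HWE test is the standard exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed, given
the allele totals), computed on individuals with non-missing genotypes,
without mid-p correction. Idempotence of the filter holds whenever the
Bonferroni divisor is fixed explicitly; with the divisor defaulting to the
current SNP count a second pass uses a laxer threshold, which is why the
analysis scripts pass the window size once.

## Haplotype classification trees

Greedy binary recursive partitioning on haplotype rows (two per
individual) with the Gini criterion and the mutation indicator as target.
Determinism: ties between equally scoring splits are broken by lowest
genomic position; a SNP never recurs on a root-to-leaf path. Stopping
rules: `min_leaf_haplotypes` (default 2), `max_depth` (default 5) and a
per-split node-local impurity-decrease threshold (`complexity_penalty`,
default 0). The defaults are liberal — with very few carrier haplotypes
the bias-variance trade-off of further splits is genuinely ambiguous, and
judgment-based early stopping is common practice — so fixtures and
analyses pin depth (and, where background noise splits would be cosmetic,
a small penalty of about 5e-4) explicitly. Missing alleles route down the
branch that received the majority of the training haplotypes at that node,
and such routings are counted on the prediction report.

A haplotype routed to a leaf receives the leaf's mutation proportion
`n_mut/(n_ref + n_mut)` as its carrier probability; an individual's dosage
is the sum over its two haplotypes; best-guess carrier status rounds at
probability 0.5. Dosages, not best guesses, feed the association models.

## r² estimators

* **Concordance (phi²)**: the squared Pearson correlation of two binary
  indicators, computed in closed form from the 2x2 agreement table, with a
  BCa ("adjusted bootstrap percentile") CI over individuals (default 2,000
  resamples, seeded).
* **LOOCV**: leaves out one *individual* (both haplotypes) at a time,
  refits the predictor, and predicts the held-out haplotypes. The primary
  metric is the squared correlation between predicted carrier
  probabilities and the true mutation indicator across haplotypes; the
  best-guess concordance table is reported alongside, because the two can
  differ materially and published summaries do not always say which scale
  was used.
* **Multi-marker proxy r²**: joint haplotype frequencies over the proxy
  SNPs plus the focal site, by direct counting when phase is available and
  otherwise by an EM over diploid genotypes (uniform initialisation, 100
  iterations maximum, 1e-8 log-likelihood tolerance; the log-likelihood is
  non-decreasing and the EM equals counting when no individual is
  doubly heterozygous). The proxy is the SNP-pattern maximising the
  standard two-locus r² with the focal allele.
* **Oversampling adjustment**: when the reference deliberately over-samples
  carriers, the population-scale expected number of mutation-bearing
  founder copies is `n_base + n_extra * base_freq`, and the adjusted r² is
  that expectation over all founder copies including the observed
  mutation-free ones. With 2 base carriers, 93 enriched individuals at
  base frequency 0.0034 and one mutation-free founder copy this gives
  2.32/3.32 ≈ 0.70.

## Misclassification correction

`v = 1 + (w − 1)/t` for relative risks (odds or hazard ratios, treating
both as risk ratios under the rare-disease approximation), pointwise
`a = g + (f − g)/t` for cumulative-risk curves (clipped to [0, 1] with a
warning; clipping can transiently break monotonicity at a step where only
the non-carrier curve jumps), and multiplication by the imputation r² for
carrier frequencies. Sensitivity `t` and imputation r² are deliberately
distinct parameters: `t` is estimated as the positive predictive value
tp/(tp + fp) of a genotyped validation table and drives the effect and
curve corrections; r² drives only the frequency adjustment.

CI inflation uses a parametric bootstrap: the effect is drawn normal on
the log (coefficient) scale, the sensitivity normal truncated to
(1e-6, 1], and the percentile interval of `v* = 1 + (exp(beta*) − 1)/t*`
is reported. Drawing the inflating quantity from the sensitivity
distribution (rather than the r² distribution) is the default because the
point correction itself uses `t`; the caller can pass any (mean, se) pair.
The function default is 10^6 iterations; tests and analysis scripts use
10^5, which already gives endpoint Monte-Carlo error well below the
reporting precision.

## Association models

Logistic regression (maximum likelihood via statsmodels) for case-control
odds ratios; Kaplan-Meier curves, a log-rank test, and Cox proportional
hazards (lifelines, Efron ties) on the age scale for age-specific risk.
One-sided p-values are oriented toward increased risk; CIs are two-sided
Wald. Separation and non-convergence are flagged on the result rather than
raised. No left truncation at cohort entry is applied — a divergence risk
when comparing with designs that model delayed entry. The
prevalent/incident split truncates follow-up at the survey age (prevalent
analysis) or excludes pre-survey cases (incident analysis) to probe
survivor bias.

## Pleiotropy scan

Per-phenotype one-sided Z statistics are combined over all `2^K − 1`
subsets as `Z_S = Σ w_k Z_k / sqrt(w_S' Σ_S w_S)`, with weights
`sqrt(n_eff)`, `n_eff = 4/(1/n_cases + 1/n_controls)`. The correlation of
two Z statistics under shared subjects is approximated by

```
corr(Zi, Zj) = (m1/(n1i·n1j) + m0/(n0i·n0j))
               / sqrt((1/n1i + 1/n0i)(1/n1j + 1/n0j))
```

with `m1` shared cases and `m0` shared controls — reducing, for fully
shared controls and disjoint cases, to
`sqrt(n1i·n1j/((n1i+n0)(n1j+n0)))`; the formula is validated against a
simulation oracle. Exhaustive enumeration is used up to K = 20 (16,383
subsets at K = 14 is trivial); the maximised statistic's p-value is the
Monte-Carlo tail probability of the maximum under `Z ~ MVN(0, Σ)` (default
10^5 draws, seeded), which is exact in the limit and conservative by the
`(1 + exceed)/(n_mc + 1)` convention. Fixing one subset reduces the method
to a generalised-least-squares meta-analysis whose combined standard error
correctly inflates under shared subjects.

## Ancestry smoothing

Each retained individual's smoothed carrier frequency is the mean expected
dosage over its k nearest retained neighbours by Euclidean distance in raw
PC1/PC2 units (the query point included, so k = n reproduces the global
mean exactly), multiplied by the r² adjustment. Exclusions (e.g. ancestry
fraction > 0.25) are applied before the neighbour search, so excluded
individuals neither receive nor contribute values. Neighbour ties are
broken by sample index. The full-cohort neighbourhood of 2,000 corresponds
to roughly 1/40 of an ~80k cohort; smaller synthetic cohorts scale k as
`max(50, n/40)`. The PCA helper centres and scales on a fit subset and
projects everyone with the fit subset's loadings, dropping constant
columns with a warning.

## Problem sizes in tests and analyses

The packaged analyses run at desk scale by design: reference panels of
2,370 haplotypes (matching the enriched-reference marginals), cohorts of
30,000–100,000 individuals for parameter-recovery and consistency checks
(50 replicates for CI coverage, 20 seeds for the correction round-trip at
200,000 haplotypes), 10^5 bootstrap/Monte-Carlo draws, and 10,000–20,000
individuals for smoothing fields. These sizes give Monte-Carlo standard
errors comfortably below the tolerances asserted.

## Known limitations

* Single-origin assumption throughout: recurrent mutation or imperfect
  specificity (`P(X=1|Y=0) > 0`) is out of scope for the correction.
* The tree stopping rule for later masking rounds is a parameter, not a
  discovery; real analyses stopped by judgment.
* The shared-subject covariance is a first-order approximation; exact
  finite-sample covariance under covariate adjustment is not modelled.
* Model-internal imputation quality metrics of HMM imputation software
  (the "info" score) are not reimplemented; all quality metrics here are
  data-level r² estimators, which is why enriched-panel in-sample values
  exceed externally validated ones until the oversampling adjustment is
  applied.
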
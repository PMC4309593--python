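# founderhap

Rare-variant imputation hinges on a simple population-genetic fact: a
mutation that arose once in history sits on a single ancestral ("founder")
haplotype. The haplotype is then **perfectly specific** for the mutation —
nobody carries the mutation without the haplotype — but **imperfectly
sensitive**: a fraction `1 − t` of haplotype copies predate or escaped the
mutation. `founderhap` is a pipeline for studying such variants in large
genotyped cohorts where the mutation itself was never assayed:

* identify the founder haplotype in a phased, carrier-enriched reference
  panel with classification trees (CART over haplotypes), and predict
  carrier dosage in a target cohort;
* quantify prediction quality with several r² estimators — leave-one-out
  cross-validation, concordance (phi²) with a genotyped validation subset,
  an EM-based multi-marker haplotype-proxy r², and an adjustment for
  deliberate carrier over-sampling in the reference;
* correct association results for the misclassification that incomplete LD
  induces;
* scan many phenotypes for pleiotropy with a subset-based statistic that
  accounts for shared cases and controls;
* smooth carrier frequency over ancestry-PC space by k-nearest-neighbour
  averaging.

A synthetic-data module (`founderhap.synthio`) generates phased panels,
enriched reference samples, multi-phenotype case-control/survival tables
and PC fields with exactly this structure, so the whole pipeline is
testable without any cohort access.

## The misclassification correction

Let `Z`, `X`, `Y` indicate disease, mutation carriage and founder-haplotype
carriage, with `a = P(Z=1|X=1)`, `b = P(Z=1|X=0)`, `f = P(Z=1|Y=1)`,
`g = P(Z=1|Y=0)`. Perfect specificity gives `g = b`, and
`f = a·t + b·(1−t)` with `t = P(X=1|Y=1)`. The observed haplotype-level
relative risk `w = f/g` therefore relates to the true carrier relative risk
`v = a/b` by `w = t·v + 1 − t`, i.e.

```
v = 1 + (w − 1)/t
```

The same algebra corrects cumulative-risk curves pointwise,
`a(age) = g(age) + (f(age) − g(age))/t`, while carrier *frequencies*
estimated from imputed dosages are corrected multiplicatively by the
imputation r². Confidence intervals for `v` come from a parametric
bootstrap over the log-scale effect and the sensitivity estimate.

## Worked example

```python
from founderhap.cart import fit_haplotype_tree, predict_dosage
from founderhap.impeval import loocv_r2
from founderhap.misclass import correct_relative_risk
from founderhap.synthio import enriched_reference_fixture

panel, truth = enriched_reference_fixture()   # 2,370 phased haplotypes
tree = fit_haplotype_tree(panel, truth)
print(tree.snps_used)
best = predict_dosage(tree, panel).hap_p >= 0.5
print(int((best & truth.x).sum()), int((best & ~truth.x).sum()),
      int((~best & truth.x).sum()))
print(round(correct_relative_risk(2.52, 15 / 26), 2))
```

prints

```
['snp0020', 'snp0028', 'snp0036']
24 2 0
3.63
```

The tree finds the three signature SNPs and recovers all 24
mutation-bearing haplotypes; its only errors are the 2 founder copies that
lack the mutation — the irreducible cost of tagging a mutation by its
haplotype. An observed odds ratio of 2.52, diluted by a sensitivity of
15/26, corrects to 3.63.

The numbered scripts under `analysis/` walk the full pipeline on synthetic
data (simulation → SNP QC → founder trees with iterative masking →
imputation-quality r² → LD-corrected prostate-cancer risk → pleiotropy scan
→ ancestry map), each printing a short narrative and writing its tables
under `results/`.

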
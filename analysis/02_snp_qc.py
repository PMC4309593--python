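#!/usr/bin/env python
"""Pre-imputation SNP QC on a 186-SNP window around the focal variant.

Applies the call-rate (< 0.95) and exact Hardy-Weinberg
(p < 0.05/186) removal rules to a window engineered with known failures,
and writes the per-SNP report.
"""

import numpy as np
import pandas as pd

from founderhap.core import HaplotypePanel
from founderhap.panel_io import QCParams, qc_filter

rng = np.random.default_rng(7)
n, m = 1000, 186
geno = rng.binomial(2, rng.uniform(0.05, 0.5, size=m), size=(n, m))
missing = np.zeros((n, m), dtype=bool)
for j in range(10):                  # 10 SNPs with depressed call rate
    missing[: int(n * 0.08), j] = True
for j in range(10, 16):              # 6 SNPs far from Hardy-Weinberg
    geno[:, j] = 1

hapa, hapb = (geno >= 1).astype(np.int8), (geno == 2).astype(np.int8)
alleles = np.empty((2 * n, m), dtype=np.int8)
alleles[0::2], alleles[1::2] = hapa, hapb
mask = np.zeros_like(alleles, dtype=bool)
mask[0::2], mask[1::2] = missing, missing
panel = HaplotypePanel(
    alleles=alleles,
    snps=pd.DataFrame({"id": [f"snp{j:04d}" for j in range(m)], "chrom": "17",
                       "pos": 46_684_000 + 4000 * np.arange(m),
                       "ref": "A", "alt": "G"}),
    samples=[f"ind{i:05d}" for i in range(n)],
    missing=mask,
)

filtered, report = qc_filter(panel, QCParams())
report.to_csv("results/02_qc_report.tsv", sep="\t", index=False)

n_removed = int(report["removed"].sum())
print(f"QC on {m} SNPs: removed {n_removed} "
      f"({(report['reason'] == 'call_rate').sum()} call rate, "
      f"{(report['reason'] == 'hwe').sum()} Hardy-Weinberg), "
      f"leaving {filtered.n_snps} SNPs passing QC")
print("Report written to results/02_qc_report.tsv")
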
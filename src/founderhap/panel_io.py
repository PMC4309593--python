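"""Phased-VCF and table I/O plus pre-imputation SNP quality control.

QC mirrors conventional GWAS practice for a window around a focal rare
variant: drop SNPs with overall call rate < 0.95 or an exact Hardy-Weinberg
p-value below a Bonferroni-corrected threshold (0.05 divided by the number
of SNPs tested).  Removal uses strict inequalities; the HWE test is the
standard exact conditional test without mid-p correction, computed on
individuals with non-missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

from .core import HaplotypePanel


@dataclass
class QCParams:
    """SNP QC thresholds.

    ``hwe_alpha_family`` is the family-wise level before Bonferroni
    division by ``hwe_n_tests`` (defaults to the number of SNPs tested, as
    the exact quotient, not a truncated printed value).
    """

    call_rate_min: float = 0.95
    hwe_alpha_family: float = 0.05
    hwe_n_tests: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must lie in (0, 1]")
        if not 0 < self.hwe_alpha_family < 1:
            raise ValueError("hwe_alpha_family must lie in (0, 1)")


def write_phased_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write the panel as a minimal phased VCF 4.2 (one ALT per record)."""
    miss = panel.missing_mask()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, snp in panel.snps.iterrows():
            fields = [
                str(snp["chrom"]),
                str(int(snp["pos"])),
                str(snp["id"]),
                str(snp["ref"]),
                str(snp["alt"]),
                ".",
                ".",
                ".",
                "GT",
            ]
            col = panel.alleles[:, j]
            mcol = miss[:, j]
            gts = [
                f"{'.' if mcol[2 * i] else col[2 * i]}|"
                f"{'.' if mcol[2 * i + 1] else col[2 * i + 1]}"
                for i in range(panel.n_individuals)
            ]
            fh.write("\t".join(fields + gts) + "\n")


def read_phased_vcf(path: str) -> HaplotypePanel:
    """Read a phased, biallelic VCF into a haplotype panel.

    Raises on any unphased diploid genotype ("/" separator) or
    multi-allelic record, naming the offending record.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    alleles_rows: list[np.ndarray] = []
    missing_rows: list[np.ndarray] = []
    recs: list[dict] = []
    for v in vcf:
        label = f"{v.CHROM}:{v.POS} ({v.ID or '.'})"
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record not supported: {label}")
        col = np.zeros(2 * len(samples), dtype=np.int8)
        mis = np.zeros(2 * len(samples), dtype=bool)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if not phased and not (a < 0 and b < 0):
                raise ValueError(f"unphased genotype for sample {samples[i]} at {label}")
            for k, al in enumerate((a, b)):
                if al < 0:
                    mis[2 * i + k] = True
                else:
                    col[2 * i + k] = al
        alleles_rows.append(col)
        missing_rows.append(mis)
        recs.append(
            {"id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM, "pos": v.POS,
             "ref": v.REF, "alt": v.ALT[0]}
        )
    vcf.close()
    alleles = np.column_stack(alleles_rows)
    missing = np.column_stack(missing_rows)
    return HaplotypePanel(
        alleles=alleles,
        snps=pd.DataFrame(recs),
        samples=samples,
        missing=missing if missing.any() else None,
    )


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities no larger than that of the observed
    configuration (no mid-p correction).
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or int(c) != c:
            raise ValueError("counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het = h | allele counts) up to a common constant
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = int(n_het)
    p_obs = p[np.flatnonzero(hets == obs)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def genotype_counts(panel: HaplotypePanel, j: int) -> tuple[int, int, int, int]:
    """Per-SNP (hom_ref, het, hom_alt, n_missing_individuals) counts."""
    col = panel.alleles[:, j].reshape(-1, 2)
    mis = panel.missing_mask()[:, j].reshape(-1, 2).any(axis=1)
    ok = col[~mis]
    s = ok.sum(axis=1)
    return (
        int((s == 0).sum()),
        int((s == 1).sum()),
        int((s == 2).sum()),
        int(mis.sum()),
    )


def qc_filter(
    panel: HaplotypePanel, params: QCParams | None = None
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Remove SNPs failing call-rate or Hardy-Weinberg thresholds.

    Returns the filtered panel and a per-SNP report
    (snp_id, call_rate, hwe_p, removed, reason).  Idempotent.
    """
    params = params or QCParams()
    n_tests = params.hwe_n_tests if params.hwe_n_tests else panel.n_snps
    hwe_threshold = params.hwe_alpha_family / n_tests
    rows = []
    keep = np.ones(panel.n_snps, dtype=bool)
    for j in range(panel.n_snps):
        hr, het, ha, n_mis = genotype_counts(panel, j)
        n_called = hr + het + ha
        call_rate = n_called / panel.n_individuals
        hwe_p = hwe_exact_pvalue(hr, het, ha) if n_called > 0 else float("nan")
        reasons = []
        if call_rate < params.call_rate_min:
            reasons.append("call_rate")
        if n_called > 0 and hwe_p < hwe_threshold:
            reasons.append("hwe")
        removed = bool(reasons)
        keep[j] = not removed
        rows.append(
            {
                "snp_id": panel.snps["id"].iloc[j],
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "removed": removed,
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    return panel.subset_snps(keep), report


def write_truth_tsv(truth, samples: list[str], path: str) -> None:
    """Per-haplotype founder/mutation truth as TSV (2 rows per individual)."""
    n = len(truth.y)
    df = pd.DataFrame(
        {
            "sample_id": [samples[i // 2] for i in range(n)],
            "haplotype": [i % 2 for i in range(n)],
            "founder_haplotype": truth.y.astype(int),
            "mutation": truth.x.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
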
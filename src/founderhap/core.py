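"""Core data containers shared across the pipeline.

The central object is a :class:`HaplotypePanel`: a phased, biallelic allele
matrix with two consecutive rows per individual (0 = REF, 1 = ALT) plus SNP
metadata.  :class:`FocalTruth` carries the per-haplotype founder-haplotype
indicator ``y`` and mutation indicator ``x`` for a focal rare variant; the
generative assumption throughout is that the mutation arose once, on a single
ancestral haplotype, so the founder haplotype is perfectly specific
(``x = 1`` implies ``y = 1``) but imperfectly sensitive (a fraction ``1 - t``
of founder copies lack the mutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SNP_COLUMNS = ("id", "chrom", "pos", "ref", "alt")


@dataclass
class HaplotypePanel:
    """Phased binary allele matrix: rows = haplotypes, columns = SNPs.

    Parameters
    ----------
    alleles
        int8 matrix of shape ``(2 * n_individuals, n_snps)``; 0 = REF,
        1 = ALT.  Haplotypes ``2i`` and ``2i + 1`` belong to individual ``i``.
    snps
        DataFrame with columns ``id, chrom, pos, ref, alt``; ``pos`` is
        1-based and strictly increasing within each chromosome.
    samples
        Individual identifiers, one per pair of rows.
    missing
        Optional boolean mask, same shape as ``alleles``; True marks a
        missing allele call.
    """

    alleles: np.ndarray
    snps: pd.DataFrame
    samples: list[str]
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (2 per individual)")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError("row count must be 2 * len(samples)")
        if list(self.snps.columns[:5]) != list(SNP_COLUMNS):
            self.snps = self.snps[list(SNP_COLUMNS)]
        if self.alleles.shape[1] != len(self.snps):
            raise ValueError("column count must equal len(snps)")
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chrom")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.alleles.shape:
                raise ValueError("missing mask shape mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean missingness mask (all-False when no mask is stored)."""
        if self.missing is None:
            return np.zeros_like(self.alleles, dtype=bool)
        return self.missing

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given SNP ids (error on unknown ids)."""
        lookup = {s: i for i, s in enumerate(self.snps["id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def subset_snps(self, keep: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to SNP columns ``keep`` (bool mask or indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypePanel(
            alleles=self.alleles[:, keep],
            snps=self.snps.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
            missing=None if self.missing is None else self.missing[:, keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given individual indices (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        rows = np.ravel(np.column_stack([2 * keep, 2 * keep + 1]))
        return HaplotypePanel(
            alleles=self.alleles[rows],
            snps=self.snps.reset_index(drop=True),
            samples=[self.samples[i] for i in keep],
            missing=None if self.missing is None else self.missing[rows],
        )


@dataclass
class FocalTruth:
    """Per-haplotype founder (``y``) and mutation (``x``) indicators.

    Perfect specificity of the founder haplotype is enforced: every
    mutation-bearing haplotype lies on the founder background.
    """

    y: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=bool)
        self.x = np.asarray(self.x, dtype=bool)
        if self.y.shape != self.x.shape:
            raise ValueError("x and y must have the same length")
        if np.any(self.x & ~self.y):
            raise ValueError("perfect specificity violated: x=1 requires y=1")

    @property
    def t_realized(self) -> float:
        """Realised sensitivity #{x=1}/#{y=1} (nan when no founder copies)."""
        ny = int(self.y.sum())
        return float(self.x.sum()) / ny if ny else float("nan")

    def subset(self, hap_rows: np.ndarray) -> "FocalTruth":
        return FocalTruth(self.y[hap_rows], self.x[hap_rows])

    def subset_individuals(self, keep: np.ndarray) -> "FocalTruth":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        rows = np.ravel(np.column_stack([2 * keep, 2 * keep + 1]))
        return self.subset(rows)

    def individual_carrier(self) -> np.ndarray:
        """Per-individual mutation-carrier indicator (either haplotype)."""
        return self.x.reshape(-1, 2).any(axis=1)

    def dosage(self) -> np.ndarray:
        """Per-individual true mutation dosage in {0, 1, 2}."""
        return self.x.reshape(-1, 2).sum(axis=1).astype(float)


@dataclass
class ConcordanceTable:
    """2x2 agreement table between predicted and true carrier status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """The table as paired 0/1 vectors (predicted, true)."""
        pred = np.concatenate(
            [np.ones(self.tp + self.fp), np.zeros(self.fn + self.tn)]
        )
        true = np.concatenate(
            [np.ones(self.tp), np.zeros(self.fp), np.ones(self.fn), np.zeros(self.tn)]
        )
        return pred, true


@dataclass
class R2Estimate:
    """An r² estimate with optional bootstrap CI and a method tag."""

    value: float
    method: str
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            # allow tiny numerical slack from bootstrap interpolation
            if not (self.ci_low <= self.value + 1e-9 and self.value - 1e-9 <= self.ci_high):
                raise ValueError("point estimate outside its CI")


@dataclass
class EffectEstimate:
    """A relative-risk style effect (OR or HR) on the log scale.

    ``w`` is the observed haplotype-level relative risk; after the
    incomplete-LD correction ``v = 1 + (w - 1)/t`` the corrected value is
    stored in ``v``.
    """

    w: float
    beta: float
    se_beta: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    kind: str = "OR"
    v: float | None = None
    v_ci_low: float | None = None
    v_ci_high: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def z(self) -> float:
        return self.beta / self.se_beta if self.se_beta > 0 else float("inf")


@dataclass
class RiskCurve:
    """Cumulative risk F(age) = 1 - S(age) on a common age grid."""

    age: np.ndarray
    risk: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.risk = np.asarray(self.risk, dtype=float)
        if self.age.shape != self.risk.shape:
            raise ValueError("age and risk must align")
        if np.any(np.diff(self.age) < 0):
            raise ValueError("age grid must be non-decreasing")
        if np.any((self.risk < -1e-12) | (self.risk > 1 + 1e-12)):
            raise ValueError("risk must lie in [0, 1]")
        if np.any(np.diff(self.risk) < -1e-9):
            # the LD correction can transiently invert a step when the
            # non-carrier curve jumps and the carrier curve does not
            warnings.warn("cumulative risk is not monotone", RuntimeWarning)
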
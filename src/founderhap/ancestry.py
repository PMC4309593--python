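"""Carrier-frequency smoothing over ancestry-PC space.

For each retained individual the smoothed carrier frequency is the mean
expected dosage over its k nearest retained neighbours (Euclidean distance
in PC1/PC2, the query point included), optionally multiplied by an
imputation-r² factor to adjust for incomplete LD.  Individuals excluded by
an ancestry-fraction filter neither receive nor contribute values.
Neighbour ties are broken by sample index, making the field deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class SmoothedField:
    """Smoothed per-individual carrier frequencies (nan where excluded)."""

    values: np.ndarray
    k: int
    r2_adjust: float
    excluded: np.ndarray


def knn_carrier_frequency(
    pc_coords: np.ndarray,
    dosages: np.ndarray,
    k: int,
    r2_adjust: float = 1.0,
    exclusion_mask: np.ndarray | None = None,
) -> SmoothedField:
    """Mean dosage over the k nearest retained neighbours, times r2_adjust.

    For a rare variant the mean expected dosage approximates the carrier
    frequency.  With k equal to the number of retained individuals every
    value equals the global retained mean times the adjustment (exact
    conservation).
    """
    coords = np.asarray(pc_coords, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("pc_coords must be (n, 2)")
    n = coords.shape[0]
    excl = (
        np.zeros(n, dtype=bool)
        if exclusion_mask is None
        else np.asarray(exclusion_mask, dtype=bool)
    )
    retained = np.flatnonzero(~excl)
    if k < 1 or k > len(retained):
        raise ValueError(f"k must lie in [1, {len(retained)}]")

    rc = coords[retained]
    rd = dosages[retained]
    values = np.full(n, np.nan)
    # chunked exact search with lexicographic (distance, index) tie-break
    nr = len(retained)
    chunk = max(1, int(2e7 // max(nr, 1)))
    for start in range(0, nr, chunk):
        block = rc[start : start + chunk]
        d2 = ((block[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2)
        for bi in range(d2.shape[0]):
            row = d2[bi]
            if k >= nr:
                sel = np.arange(nr)
            else:
                part = np.argpartition(row, k - 1)[:k]
                thresh = row[part].max()
                cand = np.flatnonzero(row <= thresh)
                sel = cand[np.lexsort((cand, row[cand]))][:k]
            values[retained[start + bi]] = rd[sel].mean() * r2_adjust
    return SmoothedField(values=values, k=k, r2_adjust=r2_adjust, excluded=excl)


def default_k(n_retained: int, k_full_scale: int = 2000, cohort_full_scale: int = 80000) -> int:
    """Neighbourhood size scaled with cohort size: k = max(50, n/40).

    The full-cohort default of 2,000 neighbours corresponds to roughly a
    fortieth of an ~80k cohort; smaller synthetic cohorts scale k
    proportionally with a floor of 50.
    """
    return max(50, min(n_retained, round(n_retained * k_full_scale / cohort_full_scale)))


def pca_fit_project(
    genotypes: np.ndarray,
    fit_subset: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """PCA fitted on a subset of individuals, all individuals projected.

    Genotype columns are centred and scaled using the fit subset's
    statistics; constant columns (in the fit subset) are dropped with a
    warning.  Fit-subset members' projected coordinates equal their fitted
    scores.
    """
    import warnings

    G = np.asarray(genotypes, dtype=float)
    fit_subset = np.asarray(fit_subset)
    if fit_subset.dtype == bool:
        fit_subset = np.flatnonzero(fit_subset)
    if len(fit_subset) == 0:
        raise ValueError("fit_subset must be non-empty")
    sub = G[fit_subset]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant-column SNPs")
    Z = (G[:, keep] - mean[keep]) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z[fit_subset])
    return pca.transform(Z)
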
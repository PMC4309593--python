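"""Subset-based multi-phenotype association scan with shared subjects.

Per-phenotype one-sided Z statistics from case-control analyses are
combined across every non-empty subset of phenotypes as a weighted sum,
standardised by a covariance matrix that accounts for shared controls and
overlapping cases.  The maximising subset is reported with a p-value
adjusted for the maximisation by Monte Carlo under the joint multivariate
normal null.  Fixing a single subset reduces the machinery to a
fixed-effects meta-analysis with shared-subject covariance.

Shared-subject covariance: with case counts n1i, n1j, control counts
n0i, n0j, m1 shared cases and m0 shared controls,

    corr(Zi, Zj) = (m1/(n1i*n1j) + m0/(n0i*n0j))
                   / sqrt((1/n1i + 1/n0i) * (1/n1j + 1/n0j))

which for fully shared controls and disjoint cases reduces to
sqrt(n1i*n1j / ((n1i + n0)*(n1j + n0))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ZPanel:
    """Per-phenotype association summaries plus subject-sharing counts."""

    names: list[str]
    z: np.ndarray
    log_or: np.ndarray
    se: np.ndarray
    n_cases: np.ndarray
    n_controls: np.ndarray
    case_overlap: np.ndarray      # K x K symmetric, diag = n_cases
    control_overlap: np.ndarray   # K x K symmetric, diag = n_controls

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.log_or = np.asarray(self.log_or, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.abs(self.z - self.log_or / self.se) > 1e-8):
            raise ValueError("Z must equal log-OR / se")


def build_z_and_cov(
    log_ors: np.ndarray,
    ses: np.ndarray,
    n_cases: np.ndarray,
    n_controls: np.ndarray,
    case_overlap: np.ndarray | None = None,
    control_overlap: np.ndarray | None = None,
    n_shared_controls: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Z vector and correlation matrix under the shared-subject approximation.

    ``n_shared_controls`` is a convenience for the common design where all
    phenotypes use one control pool; otherwise pass full overlap matrices.
    The result is symmetrised and, if needed, projected to the nearest
    positive semi-definite matrix (with a warning).
    """
    log_ors = np.asarray(log_ors, dtype=float)
    ses = np.asarray(ses, dtype=float)
    n1 = np.asarray(n_cases, dtype=float)
    n0 = np.asarray(n_controls, dtype=float)
    k = len(log_ors)
    if k < 2:
        raise ValueError("need at least two phenotypes")
    z = log_ors / ses

    if case_overlap is None:
        case_overlap = np.diag(n1)
    case_overlap = np.asarray(case_overlap, dtype=float)
    if control_overlap is None:
        if n_shared_controls is None:
            raise ValueError("supply control_overlap or n_shared_controls")
        control_overlap = np.full((k, k), float(n_shared_controls))
        np.fill_diagonal(control_overlap, n0)
    control_overlap = np.asarray(control_overlap, dtype=float)
    for ov, tot in ((case_overlap, n1), (control_overlap, n0)):
        lim = np.minimum.outer(tot, tot)
        if np.any(ov > lim + 1e-9):
            raise ValueError("overlap counts exceed group sizes")

    inv_var = 1.0 / n1 + 1.0 / n0
    sigma = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            num = case_overlap[i, j] / (n1[i] * n1[j]) + control_overlap[i, j] / (
                n0[i] * n0[j]
            )
            sigma[i, j] = sigma[j, i] = num / np.sqrt(inv_var[i] * inv_var[j])

    eigval = np.linalg.eigvalsh(sigma)
    if eigval.min() < -1e-10:
        warnings.warn("covariance not PSD; projecting to nearest PSD matrix")
        w, v = np.linalg.eigh(sigma)
        sigma = (v * np.maximum(w, 0.0)) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return z, sigma


def _subset_matrix(k: int, weights: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Rows = all 2^k - 1 subsets; row s maps Z to the standardised Z_S."""
    n_sub = (1 << k) - 1
    masks = ((np.arange(1, n_sub + 1)[:, None] >> np.arange(k)) & 1).astype(float)
    w = masks * weights
    denom = np.sqrt(np.einsum("si,ij,sj->s", w, sigma, w))
    return w / denom[:, None]


def subset_scan(
    z: np.ndarray,
    sigma: np.ndarray,
    weights: np.ndarray | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
    n_cases: np.ndarray | None = None,
    n_controls: np.ndarray | None = None,
) -> dict:
    """Maximise the weighted subset statistic and adjust p for the maximum.

    Z_S = sum_{k in S} w_k Z_k / sqrt(w_S' Sigma_S w_S); default weights are
    sqrt of the effective sample size 4/(1/n_cases + 1/n_controls) (equal
    weights if sizes are not given).  The adjusted one-sided p-value is the
    Monte-Carlo tail probability of max_S Z_S under Z ~ MVN(0, Sigma).
    """
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    k = len(z)
    if k > 20:
        raise ValueError("exhaustive enumeration limited to K <= 20")
    eigmin = np.linalg.eigvalsh(sigma).min()
    if eigmin < -1e-8:
        raise ValueError("covariance matrix is not positive semi-definite")
    if weights is None:
        if n_cases is not None and n_controls is not None:
            neff = 4.0 / (1.0 / np.asarray(n_cases) + 1.0 / np.asarray(n_controls))
            weights = np.sqrt(neff)
        else:
            weights = np.ones(k)
    weights = np.asarray(weights, dtype=float)

    S = _subset_matrix(k, weights, sigma)
    stats_all = S @ z
    best = int(np.argmax(stats_all))
    best_mask = best + 1
    best_subset = [i for i in range(k) if (best_mask >> i) & 1]
    z_max = float(stats_all[best])

    p_unadj = float(stats.norm.sf(z_max))
    if k == 1:  # a single candidate subset carries no multiplicity
        return {
            "best_subset": best_subset,
            "statistic": z_max,
            "p_adjusted": p_unadj,
            "p_unadjusted_best": p_unadj,
        }

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(k))
    exceed = 0
    chunk = max(1, min(n_mc, int(2e8 // max(S.shape[0], 1))))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        draws = rng.standard_normal((b, k)) @ L.T
        maxima = (draws @ S.T).max(axis=1)
        exceed += int((maxima >= z_max).sum())
        done += b
    p_adj = (1 + exceed) / (n_mc + 1)
    return {
        "best_subset": best_subset,
        "statistic": z_max,
        "p_adjusted": float(p_adj),
        "p_unadjusted_best": p_unadj,
    }


def fixed_subset_meta(
    z: np.ndarray,
    sigma: np.ndarray,
    subset: list[int],
    log_ors: np.ndarray,
    ses: np.ndarray,
) -> dict:
    """Inverse-variance meta-analysis of one fixed subset with covariance.

    The combined log-OR is the generalised-least-squares mean of the subset
    log-ORs under covariance V (V_ij = sigma_ij * se_i * se_j); shared
    subjects inflate the combined standard error relative to independence.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = np.asarray(subset, dtype=int)
    b = np.asarray(log_ors, dtype=float)[idx]
    s = np.asarray(ses, dtype=float)[idx]
    V = np.asarray(sigma, dtype=float)[np.ix_(idx, idx)] * np.outer(s, s)
    Vinv1 = np.linalg.solve(V, np.ones(len(idx)))
    denom = float(np.ones(len(idx)) @ Vinv1)
    beta = float(b @ Vinv1) / denom
    se = float(np.sqrt(1.0 / denom))
    zc = beta / se
    return {
        "log_or": beta,
        "or": float(np.exp(beta)),
        "se": se,
        "z": float(zc),
        "p_one_sided": float(stats.norm.sf(zc)),
    }


def multi_cancer_indicators(
    phenotype_table: pd.DataFrame,
    cancer_cols: list[str],
    prostate_col: str | None = None,
) -> pd.DataFrame:
    """Derived binary phenotypes: any, exactly-one, two-or-more, prostate-plus.

    ``cancer_cols`` are the per-cancer 0/1 indicator columns (excluding
    prostate unless it should count toward the totals).  The result carries
    one row per individual with the four indicators plus the cancer count.
    """
    counts = phenotype_table[cancer_cols].to_numpy(dtype=int).sum(axis=1)
    out = pd.DataFrame(index=phenotype_table.index)
    out["n_cancers"] = counts
    out["any_cancer"] = (counts >= 1).astype(int)
    out["exactly_one"] = (counts == 1).astype(int)
    out["two_or_more"] = (counts >= 2).astype(int)
    if prostate_col is not None:
        prost = phenotype_table[prostate_col].to_numpy(dtype=int)
        out["prostate_plus_other"] = ((prost == 1) & (counts >= 1)).astype(int)
    return out
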
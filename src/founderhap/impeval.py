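"""Imputation / carrier-prediction quality metrics.

Four r² estimators with distinct roles:

* ``concordance_r2`` — phi² (squared Pearson correlation of two binary
  indicators) of a predicted-vs-genotyped 2x2 carrier table, with a
  BCa bootstrap CI over individuals.
* ``loocv_r2`` — leave-one-individual-out cross-validation of a carrier
  predictor on the reference panel, scored per haplotype.
* ``multimarker_proxy_r2`` — LD r² between the focal allele and its best
  multi-SNP haplotype proxy, with haplotype frequencies from direct phased
  counting or from an EM over unphased genotypes.
* ``adjust_r2_oversampling`` — downward correction of a reference-panel r²
  when mutation carriers were deliberately enriched: at population scale the
  expected ratio of mutation-bearing to all founder-haplotype copies is
  restored.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Callable

import numpy as np
from scipy import stats

from .cart import TreeFitParams, fit_haplotype_tree, predict_dosage
from .core import ConcordanceTable, FocalTruth, HaplotypePanel, R2Estimate


def phi2(table: ConcordanceTable) -> float:
    """Closed-form phi² of a 2x2 table; 0 with a warning on a degenerate margin."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    denom = (tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
    if denom == 0:
        warnings.warn("degenerate margin in concordance table; r2 defined as 0")
        return 0.0
    return float((tp * tn - fp * fn) ** 2 / denom)


def concordance_r2(
    table: ConcordanceTable,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> R2Estimate:
    """phi² of a predicted-vs-true carrier table with a BCa bootstrap CI.

    Resampling is over individuals (rows of the expanded paired 0/1
    vectors), using the adjusted bootstrap percentile (BCa) method.
    """
    value = phi2(table)
    ci_low = ci_high = None
    if value > 0 and n_boot > 0:
        pred, true = table.expand()

        def stat(p, t):
            tp = int(((p == 1) & (t == 1)).sum())
            fp = int(((p == 1) & (t == 0)).sum())
            fn = int(((p == 0) & (t == 1)).sum())
            tn = int(((p == 0) & (t == 0)).sum())
            denom = (tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
            return (tp * tn - fp * fn) ** 2 / denom if denom else 0.0

        res = stats.bootstrap(
            (pred, true),
            stat,
            paired=True,
            vectorized=False,
            n_resamples=n_boot,
            confidence_level=ci_level,
            method="BCa",
            rng=np.random.default_rng(seed),
        )
        ci_low = float(min(res.confidence_interval.low, value))
        ci_high = float(max(res.confidence_interval.high, value))
    return R2Estimate(
        value=value, method="concordance", n=table.total, ci_low=ci_low, ci_high=ci_high
    )


PredictorFactory = Callable[[HaplotypePanel, FocalTruth], Callable[[HaplotypePanel], np.ndarray]]


def cart_predictor_factory(params: TreeFitParams | None = None) -> PredictorFactory:
    """Default LOOCV predictor: a haplotype classification tree."""

    def factory(panel: HaplotypePanel, truth: FocalTruth):
        tree = fit_haplotype_tree(panel, truth, params)

        def predict(target: HaplotypePanel) -> np.ndarray:
            return predict_dosage(tree, target).hap_p

        return predict

    return factory


def loocv_r2(
    ref: HaplotypePanel,
    truth: FocalTruth,
    predictor_factory: PredictorFactory | None = None,
) -> tuple[R2Estimate, ConcordanceTable]:
    """Leave-one-individual-out r² of a carrier predictor, scored per haplotype.

    Each fold removes one individual (both haplotypes), refits the predictor
    on the rest, and predicts the held-out haplotypes' carrier
    probabilities.  Returns the squared Pearson correlation between
    probabilities and the true mutation indicator, plus the best-guess
    (p >= 0.5) concordance table.
    """
    factory = predictor_factory or cart_predictor_factory()
    n = ref.n_individuals
    probs = np.empty(ref.n_haplotypes)
    all_idx = np.arange(n)
    for i in range(n):
        try:
            keep = np.delete(all_idx, i)
            predictor = factory(
                ref.subset_individuals(keep), truth.subset_individuals(keep)
            )
            held = ref.subset_individuals(np.array([i]))
            probs[2 * i : 2 * i + 2] = predictor(held)
        except Exception as err:  # noqa: BLE001 - contract: abort with fold index
            raise RuntimeError(f"predictor failed on LOOCV fold {i}") from err

    x = truth.x.astype(float)
    if np.std(probs) == 0 or np.std(x) == 0:
        warnings.warn("zero variance in LOOCV predictions or truth; r2 = 0")
        value = 0.0
    else:
        r = np.corrcoef(probs, x)[0, 1]
        value = float(r * r)
    best = probs >= 0.5
    table = ConcordanceTable(
        tp=int((best & truth.x).sum()),
        fp=int((best & ~truth.x).sum()),
        fn=int((~best & truth.x).sum()),
        tn=int((~best & ~truth.x).sum()),
    )
    return R2Estimate(value=value, method="loocv", n=ref.n_haplotypes), table


def adjust_r2_oversampling(
    n_base_carriers: int,
    n_extra: int,
    base_carrier_freq: float,
    n_false_hap_carriers: int,
) -> float:
    """Downward-adjust a carrier-enriched reference panel's r².

    At population sampling rates the extra individuals would contribute
    ``n_extra * base_carrier_freq`` expected mutation carriers; the adjusted
    r² is the expected mutation-bearing founder copies over all founder
    copies (mutation-bearing plus the observed mutation-free ones).
    """
    if not 0 < base_carrier_freq < 1:
        raise ValueError("base_carrier_freq must lie in (0, 1)")
    if min(n_base_carriers, n_extra, n_false_hap_carriers) < 0:
        raise ValueError("counts must be non-negative")
    e = n_base_carriers + n_extra * base_carrier_freq
    if e + n_false_hap_carriers == 0:
        raise ValueError("no founder-haplotype copies to adjust over")
    return float(e / (e + n_false_hap_carriers))


def estimate_base_carrier_freq(
    n_carriers: int, effective_n: float
) -> tuple[float, float]:
    """Carrier frequency and MAF from carrier count and effective sample size.

    Assumes a rare variant with no homozygotes, so MAF = carrier_freq / 2.
    """
    if effective_n <= 0:
        raise ValueError("effective_n must be positive")
    cf = n_carriers / effective_n
    return float(cf), float(cf / 2.0)


# ---------------------------------------------------------------------------
# haplotype-frequency estimation and the multi-marker proxy r²
# ---------------------------------------------------------------------------

def haplotype_freqs_phased(haps: np.ndarray) -> np.ndarray:
    """Haplotype frequencies over K sites by direct counting of phased rows."""
    haps = np.asarray(haps, dtype=int)
    k = haps.shape[1]
    idx = haps @ (1 << np.arange(k))
    freqs = np.bincount(idx, minlength=1 << k).astype(float)
    return freqs / freqs.sum()


def haplotype_freqs_em(
    genotypes: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, list[float]]:
    """EM haplotype-frequency estimates from unphased diploid genotypes.

    ``genotypes`` is (n_individuals, K) with entries 0/1/2.  Uniform
    initialisation; returns frequencies over all 2**K haplotypes plus the
    log-likelihood trace (non-decreasing by construction of EM).
    """
    g = np.asarray(genotypes, dtype=int)
    n, k = g.shape
    n_h = 1 << k
    haps = np.array(list(itertools.product([0, 1], repeat=k)))[:, ::-1]
    uniq, counts = np.unique(g, axis=0, return_counts=True)
    # compatible ordered-unordered haplotype pairs per unique genotype
    pairs: list[list[tuple[int, int]]] = []
    for row in uniq:
        plist = []
        for i in range(n_h):
            for j in range(i, n_h):
                if np.array_equal(haps[i] + haps[j], row):
                    plist.append((i, j))
        if not plist:
            raise ValueError(f"genotype {row} incompatible with biallelic sites")
        pairs.append(plist)

    f = np.full(n_h, 1.0 / n_h)
    trace: list[float] = []
    for _ in range(max_iter):
        new = np.zeros(n_h)
        ll = 0.0
        for plist, cnt in zip(pairs, counts):
            ws = np.array([(2.0 if i != j else 1.0) * f[i] * f[j] for i, j in plist])
            tot = ws.sum()
            ll += cnt * np.log(max(tot, 1e-300))
            ws /= max(tot, 1e-300)
            for (i, j), w in zip(plist, ws):
                new[i] += cnt * w
                new[j] += cnt * w
        new /= 2.0 * n
        trace.append(float(ll))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            f = new
            break
        f = new
    return f, trace


def multimarker_proxy_r2(
    panel: HaplotypePanel,
    snp_ids: list[str],
    focal_alleles: np.ndarray,
    from_genotypes: bool = False,
) -> R2Estimate:
    """LD r² between the focal allele and its best multi-SNP haplotype proxy.

    Joint haplotype frequencies over (snp_ids + focal site) come from direct
    counting of the phased panel, or — with ``from_genotypes`` — from an EM
    over collapsed diploid genotypes.  The proxy is the SNP-pattern
    maximising r² with the focal allele; r² is the standard
    two-locus formula (D² over the product of variances).
    """
    if not snp_ids:
        raise ValueError("need at least one proxy SNP")
    focal = np.asarray(focal_alleles, dtype=int)
    if focal.shape[0] != panel.n_haplotypes:
        raise ValueError("focal allele vector must have one entry per haplotype")
    p_focal = focal.mean()
    if p_focal in (0.0, 1.0):
        raise ValueError("monomorphic focal allele")
    cols = panel.snp_index(snp_ids)
    joint = np.column_stack([panel.alleles[:, cols], focal])
    k = len(snp_ids)
    if from_genotypes:
        geno = joint.reshape(-1, 2, k + 1).sum(axis=1)
        freqs, _ = haplotype_freqs_em(geno)
    else:
        freqs = haplotype_freqs_phased(joint)

    n_pat = 1 << k
    # focal site is the highest-order bit of the joint pattern index
    pat_nofocal = freqs[:n_pat]
    pat_focal = freqs[n_pat:]
    p_f = pat_focal.sum()
    best_r2, best_pat = -1.0, None
    for h in range(n_pat):
        p_h = pat_nofocal[h] + pat_focal[h]
        if p_h <= 0 or p_h >= 1:
            continue
        d = pat_focal[h] - p_h * p_f
        r2 = d * d / (p_h * (1 - p_h) * p_f * (1 - p_f))
        if r2 > best_r2:
            best_r2, best_pat = r2, h
    if best_pat is None:
        warnings.warn("no polymorphic proxy pattern; r2 = 0")
        best_r2 = 0.0
    return R2Estimate(value=float(best_r2), method="proxy", n=panel.n_haplotypes)
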
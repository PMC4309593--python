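"""Synthetic phased panels, enriched reference samples and phenotypes.

This module generates data with the statistical structure the downstream
analyses assume: a rare mutation that arose exactly once on a single
ancestral ("founder") haplotype, so that the founder background is perfectly
specific for the mutation while only a proportion ``t`` of founder copies
actually carry it (imperfect sensitivity); a reference panel deliberately
enriched for mutation carriers; and case-control / time-to-onset phenotypes
generated under specified odds and hazard ratios with controls shared across
phenotypes.

Background haplotypes follow a first-order Markov chain over SNPs with
specified marginal ALT frequencies and a tunable adjacent-SNP allele
correlation — the simplest model with local LD.  The founder haplotype is a
fixed allele pattern (the minor allele at a small set of "signature" SNPs,
the major allele elsewhere), optionally eroded from the window edges to
mimic recombination decay of the ancestral segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import FocalTruth, HaplotypePanel


def _as_freq_vector(freqs, n_snps: int) -> np.ndarray:
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_snps, float(arr))
    if arr.shape != (n_snps,):
        raise ValueError("background_allele_freqs must be scalar or length n_snps")
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    return arr


@dataclass
class PanelSpec:
    """Parameters of a synthetic phased panel around one focal rare variant.

    ``founder_hap_freq`` is the population frequency of the ancestral
    haplotype; ``sensitivity_t`` is P(mutation | founder haplotype) per copy.
    ``founder_edge_erosion`` is the per-SNP probability, scanning inward from
    each window edge, that a founder copy reverts to its background allele
    (a geometric erosion run per edge).
    """

    n_individuals: int
    n_snps: int
    background_allele_freqs: float | Sequence[float] = 0.25
    background_ld_decay: float = 0.3
    founder_hap_freq: float = 0.005
    sensitivity_t: float = 0.96
    founder_edge_erosion: float = 0.0
    signature_snps: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        if not 0 < self.sensitivity_t <= 1:
            raise ValueError("sensitivity_t must lie in (0, 1]")
        if not 0 < self.founder_hap_freq < 1:
            raise ValueError("founder_hap_freq must lie in (0, 1)")
        if not 0 <= self.background_ld_decay < 1:
            raise ValueError("background_ld_decay must lie in [0, 1)")
        if not 0 <= self.founder_edge_erosion < 1:
            raise ValueError("founder_edge_erosion must lie in [0, 1)")
        self.background_allele_freqs = _as_freq_vector(
            self.background_allele_freqs, self.n_snps
        )
        if self.signature_snps is None:
            # signature SNPs spread over the interior of the window
            k = min(3, self.n_snps)
            idx = np.unique(
                np.round(np.linspace(0, self.n_snps - 1, k + 2)[1:-1]).astype(int)
            )
            if len(idx) < k:
                idx = np.arange(k)
            self.signature_snps = tuple(int(i) for i in idx)
        if len(set(self.signature_snps)) != len(self.signature_snps):
            raise ValueError("signature_snps must be distinct")


def _snp_table(n_snps: int, chrom: str = "17", start: int = 46_684_000,
               step: int = 4_000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{j:04d}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": start + step * np.arange(n_snps),
            "ref": "A",
            "alt": "G",
        }
    )


def _markov_background(rng: np.random.Generator, n_haps: int,
                       freqs: np.ndarray, rho: float) -> np.ndarray:
    """Binary haplotypes with given marginals and adjacent-allele correlation.

    First-order chain: corr(SNP_j, SNP_{j+1}) ~= rho, decaying as rho**d
    with distance.  Conditional probabilities are clipped to [0, 1], so the
    realised correlation can fall slightly short for extreme frequencies.
    """
    m = len(freqs)
    out = np.empty((n_haps, m), dtype=np.int8)
    u = rng.random((n_haps, m))
    out[:, 0] = u[:, 0] < freqs[0]
    for j in range(1, m):
        p_prev, p = freqs[j - 1], freqs[j]
        q_prev, q = 1 - p_prev, 1 - p
        c = rho * math.sqrt(p_prev * q_prev * p * q)
        p1 = np.clip(p + c / p_prev, 0.0, 1.0)   # P(1 | prev = 1)
        p0 = np.clip(p - c / q_prev, 0.0, 1.0)   # P(1 | prev = 0)
        cond = np.where(out[:, j - 1] == 1, p1, p0)
        out[:, j] = u[:, j] < cond
    return out


def founder_pattern(spec: PanelSpec) -> np.ndarray:
    """The fixed ancestral allele pattern the founder haplotype carries."""
    freqs = spec.background_allele_freqs
    pat = (freqs > 0.5).astype(np.int8)  # major allele everywhere
    for j in spec.signature_snps:
        pat[j] = 1 - pat[j]  # minor allele at the signature SNPs
    return pat


def simulate_panel(spec: PanelSpec) -> tuple[HaplotypePanel, FocalTruth]:
    """Draw a phased panel plus founder/mutation truth for the focal variant.

    Haplotypes with founder indicator y are Bernoulli(founder_hap_freq);
    mutation indicator x is Bernoulli(sensitivity_t) among y = 1 copies and
    identically zero among y = 0 copies (perfect specificity).
    """
    root = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    n_haps = 2 * spec.n_individuals
    alleles = _markov_background(
        rngs[0], n_haps, spec.background_allele_freqs, spec.background_ld_decay
    )

    y = rngs[1].random(n_haps) < spec.founder_hap_freq
    pat = founder_pattern(spec)
    m = spec.n_snps
    for row in np.flatnonzero(y):
        lo, hi = 0, m
        if spec.founder_edge_erosion > 0:
            # geometric erosion runs from both window edges
            while lo < m and rngs[2].random() < spec.founder_edge_erosion:
                lo += 1
            while hi > lo and rngs[2].random() < spec.founder_edge_erosion:
                hi -= 1
        alleles[row, lo:hi] = pat[lo:hi]

    x = y & (rngs[3].random(n_haps) < spec.sensitivity_t)

    panel = HaplotypePanel(
        alleles=alleles,
        snps=_snp_table(spec.n_snps),
        samples=[f"ind{i:06d}" for i in range(spec.n_individuals)],
    )
    return panel, FocalTruth(y=y, x=x)


@dataclass
class EnrichedSample:
    """A carrier-enriched subsample of a panel, with its enrichment factor."""

    panel: HaplotypePanel
    truth: FocalTruth
    enrichment: float


def sample_enriched_reference(
    panel: HaplotypePanel,
    truth: FocalTruth,
    n_carrier_individuals: int,
    n_noncarrier_individuals: int,
    seed: int = 0,
    base_carrier_freq: float | None = None,
) -> EnrichedSample:
    """Subsample exact numbers of mutation-carrier and non-carrier individuals.

    The enrichment factor is the carrier frequency in the subsample divided
    by the base carrier frequency (the full panel's, unless an external
    population value is supplied).
    """
    rng = np.random.default_rng(seed)
    carrier = truth.individual_carrier()
    carriers = np.flatnonzero(carrier)
    noncarriers = np.flatnonzero(~carrier)
    if n_carrier_individuals > len(carriers):
        raise ValueError(
            f"requested {n_carrier_individuals} carriers, only {len(carriers)} available"
        )
    if n_noncarrier_individuals > len(noncarriers):
        raise ValueError(
            f"requested {n_noncarrier_individuals} non-carriers, "
            f"only {len(noncarriers)} available"
        )
    pick = np.sort(
        np.concatenate(
            [
                rng.choice(carriers, n_carrier_individuals, replace=False),
                rng.choice(noncarriers, n_noncarrier_individuals, replace=False),
            ]
        )
    )
    n_total = n_carrier_individuals + n_noncarrier_individuals
    sample_freq = n_carrier_individuals / n_total if n_total else 0.0
    if base_carrier_freq is None:
        base_carrier_freq = carrier.mean()
    enrichment = sample_freq / base_carrier_freq if base_carrier_freq > 0 else math.inf
    return EnrichedSample(
        panel=panel.subset_individuals(pick),
        truth=truth.subset_individuals(pick),
        enrichment=float(enrichment),
    )


# ---------------------------------------------------------------------------
# engineered reference-panel fixture
# ---------------------------------------------------------------------------

def enriched_reference_fixture(
    n_individuals: int = 1185,
    n_snps: int = 57,
    n_mut: int = 24,
    n_founder_nonmut: int = 2,
    signature_snps: tuple[int, int, int] = (20, 28, 36),
    sig_counts: tuple[int, int, int] = (69, 86, 93),
    sig_overlap12: int = 4,
    sig_overlap13: int = 7,
    seed: int = 7,
) -> tuple[HaplotypePanel, FocalTruth]:
    """A panel with exact founder/mutation marginals for validation studies.

    Emulates a carrier-enriched reference panel: ``n_mut`` mutation-bearing
    haplotypes plus ``n_founder_nonmut`` founder copies without the mutation,
    all on distinct individuals, against a Markov-chain background.  The
    three signature minor alleles are individually common in the background
    (counts ``sig_counts`` for exclusive carriers plus the two pairwise
    overlaps) but never co-occur on a background haplotype, so the founder
    background — and only it — carries all three.  Greedy tree fitting must
    therefore use all three signature SNPs to isolate the founder set.
    """
    n_haps = 2 * n_individuals
    n_founder = n_mut + n_founder_nonmut
    s1, s2, s3 = signature_snps
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.4, size=n_snps)
    alleles = _markov_background(rng, n_haps, freqs, rho=0.25)

    # wipe signature columns, then place carriers deterministically
    alleles[:, [s1, s2, s3]] = 0
    founder_rows = np.arange(0, 2 * n_founder, 2)  # one copy per individual
    pat = np.zeros(n_snps, dtype=np.int8)
    pat[[s1, s2, s3]] = 1
    alleles[founder_rows] = pat

    bg_rows = np.setdiff1d(np.arange(n_haps), founder_rows)
    n1o, n2o, n3o = sig_counts
    need = n1o + n2o + n3o + sig_overlap12 + sig_overlap13
    if need > len(bg_rows):
        raise ValueError("not enough background haplotypes for signature counts")
    chosen = rng.choice(bg_rows, size=need, replace=False)
    i = 0
    for cols, cnt in [
        ((s1,), n1o),
        ((s2,), n2o),
        ((s3,), n3o),
        ((s1, s2), sig_overlap12),
        ((s1, s3), sig_overlap13),
    ]:
        rows = chosen[i : i + cnt]
        if len(cols) > 1:
            # overlap rows differ from the founder pattern only at the
            # missing signature SNP, so the split isolating the founder set
            # is unique (no tied background column)
            alleles[rows] = 0
        for col in cols:
            alleles[rows, col] = 1
        i += cnt

    y = np.zeros(n_haps, dtype=bool)
    y[founder_rows] = True
    x = np.zeros(n_haps, dtype=bool)
    x[founder_rows[:n_mut]] = True

    panel = HaplotypePanel(
        alleles=alleles,
        snps=_snp_table(n_snps),
        samples=[f"ind{i:06d}" for i in range(n_individuals)],
    )
    return panel, FocalTruth(y=y, x=x)


def add_secondary_signature(
    panel: HaplotypePanel,
    truth: FocalTruth,
    secondary_snps: tuple[int, ...] = (8, 12, 44, 50),
    primary_snps: tuple[int, ...] = (20, 28, 36),
    n_eroded_carriers: int = 4,
    sec_counts: tuple[int, ...] = (100, 130, 140, 150),
    pair_overlaps: tuple[int, ...] = (3, 5, 7),
    seed: int = 11,
) -> tuple[HaplotypePanel, FocalTruth]:
    """Overlay a second, weaker founder signature on the fixture panel.

    All founder copies except ``n_eroded_carriers`` mutation-bearing ones
    receive the minor allele at every secondary SNP; the eroded copies keep
    background alleles there.  Secondary minor alleles are individually more
    common in the background than the primary ones (counts ``sec_counts``),
    so a tree with the primary signature available prefers the primary
    SNPs, while a tree fitted after masking them recovers most — but not
    the eroded — carriers from the secondary SNPs.  ``pair_overlaps`` are
    background rows carrying the first secondary SNP together with each of
    the others (zero elsewhere), so no two secondary SNPs suffice to
    isolate the founder set.
    """
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    founder_rows = np.flatnonzero(truth.y)
    mut_rows = np.flatnonzero(truth.x)
    eroded = rng.choice(mut_rows, size=n_eroded_carriers, replace=False)
    keep = np.setdiff1d(founder_rows, eroded)
    alleles[:, list(secondary_snps)] = 0  # carrier counts are set exactly
    for col in secondary_snps:
        alleles[keep, col] = 1

    # eligible background rows: no founder and no primary-signature allele
    bg = np.setdiff1d(np.arange(panel.n_haplotypes), founder_rows)
    clean = bg[(alleles[np.ix_(bg, np.array(primary_snps))] == 0).all(axis=1)]
    need = sum(sec_counts) + sum(pair_overlaps)
    chosen = rng.choice(clean, size=need, replace=False)
    i = 0
    jobs = [((c,), n, False) for c, n in zip(secondary_snps, sec_counts)] + [
        ((secondary_snps[0], other), cnt, True)
        for other, cnt in zip(secondary_snps[1:], pair_overlaps)
    ]
    for cols, cnt, wipe in jobs:
        rows = chosen[i : i + cnt]
        if wipe:
            alleles[rows] = 0
        for col in cols:
            alleles[rows, col] = 1
        i += cnt
    out = HaplotypePanel(
        alleles=alleles, snps=panel.snps, samples=list(panel.samples)
    )
    return out, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """One phenotype: binary (logistic) or time-to-onset (Weibull PH).

    For ``kind='binary'`` the baseline is a prevalence; the effect is an
    odds ratio per dosage unit.  For ``kind='survival'`` the baseline is a
    Weibull (shape, scale in years; shape 1 = exponential) and the effect a
    hazard ratio; onset is censored at an age drawn from a normal
    distribution (``censor_mean``, ``censor_sd``).
    """

    name: str
    kind: str = "binary"
    prevalence: float = 0.05
    odds_ratio: float = 1.0
    shape: float = 1.0
    scale: float = 200.0
    hazard_ratio: float = 1.0
    censor_mean: float = 75.0
    censor_sd: float = 8.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    sex_specific: str | None = None  # "M" or "F"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "survival"):
            raise ValueError("kind must be 'binary' or 'survival'")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.odds_ratio <= 0 or self.hazard_ratio <= 0:
            raise ValueError("effect sizes must be positive")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("negative or zero baseline hazard parameters")


@dataclass
class PhenoSpec:
    """A battery of phenotypes over one cohort.

    ``shared_frailty_sd`` adds a per-individual normal random intercept
    shared by every phenotype's linear predictor, inducing cross-phenotype
    case overlap beyond what the shared dosage produces.
    """

    phenotypes: list[PhenotypeSpec]
    shared_frailty_sd: float = 0.0
    survey_age_range: tuple[float, float] = (55.0, 70.0)
    seed: int = 0


def simulate_phenotypes(
    dosages: np.ndarray,
    covariates: pd.DataFrame | None,
    spec: PhenoSpec,
) -> pd.DataFrame:
    """Simulate case status and/or age at onset for each phenotype.

    Returns one row per individual: ``sample_id``, ``sex``, ``survey_age``,
    a case indicator column per binary phenotype, and ``<name>_age`` /
    ``<name>_event`` columns per survival phenotype.
    """
    dosages = np.asarray(dosages, dtype=float)
    if np.any((dosages < 0) | (dosages > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    n = len(dosages)
    root = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(3 + len(spec.phenotypes))]

    sex = np.where(rngs[0].random(n) < 0.5, "M", "F")
    survey_age = rngs[1].uniform(*spec.survey_age_range, size=n)
    frailty = (
        rngs[2].normal(0.0, spec.shared_frailty_sd, size=n)
        if spec.shared_frailty_sd > 0
        else np.zeros(n)
    )

    out = pd.DataFrame(
        {
            "sample_id": [f"ind{i:06d}" for i in range(n)],
            "sex": sex,
            "survey_age": survey_age,
            "dosage": dosages,
        }
    )
    if covariates is not None:
        for c in covariates.columns:
            out[c] = np.asarray(covariates[c])

    for k, ph in enumerate(spec.phenotypes):
        rng = rngs[3 + k]
        eta_cov = np.zeros(n)
        for cname, beta in ph.covariate_betas.items():
            if covariates is None or cname not in covariates.columns:
                raise KeyError(f"covariate {cname!r} not supplied")
            eta_cov += beta * np.asarray(covariates[cname], dtype=float)
        eligible = (
            np.ones(n, dtype=bool) if ph.sex_specific is None else sex == ph.sex_specific
        )
        if ph.kind == "binary":
            eta = (
                math.log(ph.prevalence / (1 - ph.prevalence))
                + math.log(ph.odds_ratio) * dosages
                + eta_cov
                + frailty
            )
            p = 1.0 / (1.0 + np.exp(-eta))
            case = (rng.random(n) < p) & eligible
            out[ph.name] = case.astype(int)
        else:
            eta = math.log(ph.hazard_ratio) * dosages + eta_cov + frailty
            u = rng.random(n)
            onset = ph.scale * (-np.log(u) / np.exp(eta)) ** (1.0 / ph.shape)
            censor = np.clip(rng.normal(ph.censor_mean, ph.censor_sd, size=n), 1.0, None)
            age = np.minimum(onset, censor)
            event = (onset <= censor) & eligible
            out[f"{ph.name}_age"] = np.where(eligible, age, censor)
            out[f"{ph.name}_event"] = event.astype(int)
    return out


# ---------------------------------------------------------------------------
# PC-space carrier field
# ---------------------------------------------------------------------------

def simulate_pc_field(
    n: int,
    component_weights: Sequence[float],
    means: Sequence[Sequence[float]],
    sds: Sequence[float],
    carrier_freqs: Sequence[float],
    ancestry_fraction_component: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Individuals in 2-D ancestry-PC space from a labelled Gaussian mixture.

    Each mixture component has its own carrier frequency; carriers get
    dosage 1 (rare variant, no homozygotes).  If
    ``ancestry_fraction_component`` is given, members of that component get
    an ancestry fraction near 1 and everyone else near 0, supporting
    fraction-threshold exclusions.
    """
    w = np.asarray(component_weights, dtype=float)
    if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    coords = means[comp] + rng.normal(size=(n, 2)) * sds[comp, None]
    freqs = np.asarray(carrier_freqs, dtype=float)[comp]
    carrier = rng.random(n) < freqs
    frac = np.zeros(n)
    if ancestry_fraction_component is not None:
        frac = np.clip(
            np.where(
                comp == ancestry_fraction_component,
                rng.normal(0.9, 0.05, n),
                rng.normal(0.02, 0.02, n),
            ),
            0.0,
            1.0,
        )
    return pd.DataFrame(
        {
            "sample_id": [f"ind{i:06d}" for i in range(n)],
            "PC1": coords[:, 0],
            "PC2": coords[:, 1],
            "component": comp,
            "dosage": carrier.astype(float),
            "ancestry_fraction": frac,
        }
    )
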
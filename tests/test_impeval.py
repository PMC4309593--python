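"""r² estimators: concordance phi², LOOCV, oversampling adjustment, EM proxy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderhap.cart import TreeFitParams, fit_haplotype_tree, tree_r2, predict_dosage
from founderhap.core import ConcordanceTable, FocalTruth
from founderhap.impeval import (
    adjust_r2_oversampling,
    cart_predictor_factory,
    concordance_r2,
    estimate_base_carrier_freq,
    haplotype_freqs_em,
    haplotype_freqs_phased,
    loocv_r2,
    multimarker_proxy_r2,
    phi2,
)
from founderhap.synthio import PanelSpec, simulate_panel


class TestConcordanceR2:
    def test_validation_table_value(self):
        # 26 predicted carriers, 15 genotype-confirmed, no missed carriers
        assert phi2(ConcordanceTable(15, 11, 0, 3436)) == pytest.approx(0.575, abs=5e-4)

    def test_perfect_agreement(self):
        assert phi2(ConcordanceTable(7, 0, 0, 93)) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tp=st.integers(1, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(1, 200))
    def test_matches_vector_expansion_oracle(self, tp, fp, fn, tn):
        table = ConcordanceTable(tp, fp, fn, tn)
        pred, true = table.expand()
        if pred.std() == 0 or true.std() == 0:
            return
        expect = np.corrcoef(pred, true)[0, 1] ** 2
        assert phi2(table) == pytest.approx(expect, abs=1e-12)
        assert 0 <= phi2(table) <= 1

    def test_label_swap_invariance(self):
        a = phi2(ConcordanceTable(12, 4, 7, 100))
        b = phi2(ConcordanceTable(100, 7, 4, 12))
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_margin_warns_zero(self):
        with pytest.warns(UserWarning):
            assert phi2(ConcordanceTable(5, 0, 5, 0)) == 0.0

    def test_bootstrap_ci_brackets_value(self):
        est = concordance_r2(ConcordanceTable(15, 11, 0, 3436), n_boot=400, seed=0)
        assert est.ci_low <= est.value <= est.ci_high
        assert est.ci_high - est.ci_low < 0.6


class TestLoocv:
    def test_perfect_tag_panel_gives_r2_one(self):
        spec = PanelSpec(n_individuals=60, n_snps=6, founder_hap_freq=0.1,
                         sensitivity_t=1.0, background_allele_freqs=0.01, seed=21)
        panel, truth = simulate_panel(spec)
        # a perfect tag: signature alleles occur on founder haplotypes only
        panel.alleles[np.ix_(~truth.y, np.array(spec.signature_snps))] = 0
        assert truth.x.sum() >= 2
        est, table = loocv_r2(panel, truth)
        assert est.value == pytest.approx(1.0)
        assert table.fp == 0 and table.fn == 0

    def test_constant_predictor_scores_zero(self, small_panel):
        panel, truth = small_panel

        def zero_factory(_panel, _truth):
            return lambda target: np.zeros(target.n_haplotypes)

        with pytest.warns(UserWarning):
            est, _ = loocv_r2(panel, truth, zero_factory)
        assert est.value == 0.0

    def test_failing_predictor_reports_fold(self, small_panel):
        panel, truth = small_panel

        def broken(_panel, _truth):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            loocv_r2(panel, truth, broken)

    @pytest.mark.parametrize("seed", range(20))
    def test_loocv_never_beats_in_sample_r2(self, seed):
        spec = PanelSpec(n_individuals=120, n_snps=8, founder_hap_freq=0.08,
                         sensitivity_t=0.85, background_allele_freqs=0.15,
                         seed=300 + seed)
        panel, truth = simulate_panel(spec)
        if truth.x.sum() < 2:
            pytest.skip("too few mutation copies")
        est, _ = loocv_r2(panel, truth)
        tree = fit_haplotype_tree(panel, truth)
        hap_p = predict_dosage(tree, panel).hap_p
        r = np.corrcoef(hap_p, truth.x.astype(float))[0, 1]
        assert est.value <= r * r + 0.02


class TestOversamplingAdjustment:
    def test_enriched_panel_worked_example(self):
        # 2 base carriers, 93 enriched individuals at base frequency 0.0034,
        # one founder-haplotype copy without the mutation
        adj = adjust_r2_oversampling(2, 93, 0.0034, 1)
        assert adj == pytest.approx(2.3162 / 3.3162, abs=1e-9)
        assert round(adj, 2) == 0.70

    def test_no_false_carriers_gives_one(self):
        assert adjust_r2_oversampling(5, 100, 0.01, 0) == 1.0

    def test_direct_formula(self):
        assert adjust_r2_oversampling(0, 1000, 0.01, 10) == pytest.approx(0.5)

    def test_monotone_in_false_carriers_and_base_freq(self):
        vals = [adjust_r2_oversampling(2, 93, 0.0034, k) for k in range(4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        freqs = [adjust_r2_oversampling(2, 93, f, 1) for f in (0.001, 0.01, 0.05)]
        assert all(a < b for a, b in zip(freqs, freqs[1:]))


def test_base_carrier_freq_from_effective_n():
    cf, maf = estimate_base_carrier_freq(2, 581.2)
    assert cf == pytest.approx(0.0034, abs=5e-5)
    assert maf == pytest.approx(0.0017, abs=2.5e-5)
    assert estimate_base_carrier_freq(0, 100.0) == (0.0, 0.0)


class TestProxyR2:
    def test_perfect_single_snp_tag(self):
        rng = np.random.default_rng(0)
        spec = PanelSpec(n_individuals=100, n_snps=4, founder_hap_freq=0.1,
                         sensitivity_t=1.0, background_allele_freqs=0.01, seed=5)
        panel, truth = simulate_panel(spec)
        sig = spec.signature_snps[0]
        focal = panel.alleles[:, sig].copy()
        est = multimarker_proxy_r2(panel, [f"snp{sig:04d}"], focal)
        assert est.value == pytest.approx(1.0)

    def test_em_matches_phased_counting_when_phase_unambiguous(self):
        # no individual is heterozygous at both sites, so every genotype
        # resolves to a unique haplotype pair and EM must equal counting
        pairs = (
            [((0, 0), (0, 0))] * 40
            + [((0, 0), (0, 1))] * 25
            + [((0, 1), (0, 1))] * 20
            + [((0, 0), (1, 0))] * 15
        )
        joint = np.array([h for p in pairs for h in p])
        counted = haplotype_freqs_phased(joint)
        geno = joint.reshape(-1, 2, 2).sum(axis=1)
        em, trace = haplotype_freqs_em(geno)
        assert np.all(np.diff(trace) >= -1e-9)  # EM log-likelihood ascends
        assert np.allclose(em, counted, atol=1e-6)

    def test_em_loglik_ascends_with_ambiguous_phase(self):
        spec = PanelSpec(n_individuals=200, n_snps=3, background_allele_freqs=0.3,
                         background_ld_decay=0.5, founder_hap_freq=0.01, seed=9)
        panel, _ = simulate_panel(spec)
        geno = panel.alleles[:, :2].reshape(-1, 2, 2).sum(axis=1)
        _, trace = haplotype_freqs_em(geno)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_two_snp_hand_enumeration(self):
        # haplotypes over (snp, focal): 40x(0,0), 10x(1,0), 10x(1,1)
        import pandas as pd
        from founderhap.core import HaplotypePanel

        snp = np.array([0] * 40 + [1] * 20, dtype=np.int8)
        focal = np.array([0] * 50 + [1] * 10)
        panel = HaplotypePanel(
            alleles=snp.reshape(-1, 1),
            snps=pd.DataFrame({"id": ["s0"], "chrom": "1", "pos": [100],
                               "ref": "A", "alt": "G"}),
            samples=[f"i{k}" for k in range(30)],
        )
        est = multimarker_proxy_r2(panel, ["s0"], focal)
        # D = 10/60 - (20/60)(10/60); r2 = D^2 / (p q u v) by hand
        d = 10 / 60 - (20 / 60) * (10 / 60)
        expect = d * d / ((20 / 60) * (40 / 60) * (10 / 60) * (50 / 60))
        assert est.value == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_focal_errors(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(ValueError, match="monomorphic"):
            multimarker_proxy_r2(panel, [panel.snps["id"].iloc[0]],
                                 np.zeros(panel.n_haplotypes, dtype=int))
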
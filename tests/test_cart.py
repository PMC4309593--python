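"""Haplotype classification trees: greedy fits, masking rounds, prediction."""

import numpy as np
import pandas as pd
import pytest

from founderhap.cart import (
    TreeFitParams,
    TreeModel,
    fit_haplotype_tree,
    mask_and_refit,
    predict_dosage,
    tree_r2,
)
from founderhap.core import FocalTruth, HaplotypePanel
from founderhap.synthio import PanelSpec, simulate_panel


def _tiny_panel(alleles: np.ndarray) -> HaplotypePanel:
    n_hap, m = alleles.shape
    assert n_hap % 2 == 0
    snps = pd.DataFrame(
        {"id": [f"s{j}" for j in range(m)], "chrom": "1",
         "pos": np.arange(1, m + 1) * 10, "ref": "A", "alt": "G"}
    )
    return HaplotypePanel(alleles=alleles.astype(np.int8), snps=snps,
                          samples=[f"i{k}" for k in range(n_hap // 2)])


from tests_support import optimal_misclassification


def greedy_misclassification(panel, truth, params):
    tree = fit_haplotype_tree(panel, truth, params)
    best = predict_dosage(tree, panel).hap_p >= 0.5
    return int((best != truth.x).sum())


def test_perfect_tag_gives_single_pure_split():
    rng = np.random.default_rng(0)
    alleles = rng.integers(0, 2, size=(60, 5)).astype(np.int8)
    x = alleles[:, 2] == 1  # SNP s2 tags the mutation perfectly
    truth = FocalTruth(y=x, x=x)
    tree = fit_haplotype_tree(_tiny_panel(alleles), truth, TreeFitParams(min_leaf_haplotypes=1))
    assert tree.snps_used == ["s2"]
    assert tree.root.left.is_leaf and tree.root.right.is_leaf
    assert tree.root.left.p_mut == 1.0 and tree.root.right.p_mut == 0.0


def test_reference_fixture_reproduces_expected_error_pattern(ref_panel):
    panel, truth = ref_panel
    tree = fit_haplotype_tree(panel, truth)
    assert tree.snps_used == ["snp0020", "snp0028", "snp0036"]
    best = predict_dosage(tree, panel).hap_p >= 0.5
    assert int((best & truth.x).sum()) == 24       # all carriers recovered
    assert int((best & ~truth.x).sum()) == 2       # two founder copies sans mutation
    assert int((~best & truth.x).sum()) == 0       # no missed carriers


def test_zero_mutation_haplotypes_is_degenerate():
    alleles = np.zeros((10, 3), dtype=np.int8)
    with pytest.raises(ValueError, match="specificity|degenerate"):
        # FocalTruth itself rejects x without y; an all-zero x is degenerate
        truth = FocalTruth(y=np.zeros(10, bool), x=np.zeros(10, bool))
        fit_haplotype_tree(_tiny_panel(alleles), truth)


@pytest.mark.parametrize("seed", range(6))
def test_greedy_never_beats_brute_force_and_matches_on_small_panels(seed):
    rng = np.random.default_rng(seed)
    n_hap, m = 40, 6
    alleles = rng.integers(0, 2, size=(n_hap, m)).astype(np.int8)
    y = (alleles[:, 1] == 1) & (alleles[:, 4] == 1)
    if y.sum() == 0:
        y[:2] = True
        alleles[:2, [1, 4]] = 1
    truth = FocalTruth(y=y, x=y)
    panel = _tiny_panel(alleles)
    params = TreeFitParams(min_leaf_haplotypes=1, max_depth=3)
    greedy = greedy_misclassification(panel, truth, params)
    optimum = optimal_misclassification(alleles, truth.x, max_depth=3)
    assert greedy >= optimum
    # a 2-SNP conjunction is exactly representable at depth <= 3
    assert optimum == 0
    assert greedy == optimum


def test_monotonicity_adding_perfect_tag_never_hurts(small_panel):
    panel, truth = small_panel
    params = TreeFitParams(max_depth=4)
    base_err = greedy_misclassification(panel, truth, params)
    # append a perfectly tagging SNP column
    alleles = np.column_stack([panel.alleles, truth.x.astype(np.int8)])
    snps = pd.concat(
        [panel.snps,
         pd.DataFrame([{"id": "tag", "chrom": "17",
                        "pos": int(panel.snps['pos'].max()) + 10,
                        "ref": "A", "alt": "G"}])],
        ignore_index=True,
    )
    bigger = HaplotypePanel(alleles=alleles, snps=snps, samples=list(panel.samples))
    tag_err = greedy_misclassification(bigger, truth, params)
    assert tag_err <= base_err


@pytest.mark.parametrize("seed", range(20))
def test_round_one_tree_recovers_founder_set(seed):
    """With an intact signature the tree recovers the founder haplotype Y —
    not the mutation X — so false negatives are impossible and the positive
    set is exactly the signature-bearing haplotypes."""
    freqs = np.full(12, 0.2)
    freqs[[3, 6, 8]] = 0.01  # rare signature alleles: no background collisions
    spec = PanelSpec(n_individuals=250, n_snps=12,
                     background_allele_freqs=freqs, founder_hap_freq=0.06,
                     sensitivity_t=0.8, signature_snps=(3, 6, 8), seed=100 + seed)
    panel, truth = simulate_panel(spec)
    assert truth.y.sum() >= 20
    tree = fit_haplotype_tree(panel, truth, TreeFitParams(min_leaf_haplotypes=1))
    pos = predict_dosage(tree, panel).hap_p >= 0.5
    assert not np.any(truth.x & ~pos)       # FN = 0
    assert np.array_equal(pos, truth.y)     # positives are the founder set


class TestMaskAndRefit:
    def test_trees_share_no_snps(self, ref_panel_two_signatures):
        panel, truth = ref_panel_two_signatures
        trees = mask_and_refit(
            panel, truth, TreeFitParams(max_depth=3, complexity_penalty=5e-4), rounds=3
        )
        for a in range(len(trees)):
            for b in range(a + 1, len(trees)):
                assert set(trees[a].snps_used).isdisjoint(trees[b].snps_used)

    def test_second_round_uses_secondary_signature_and_drops_carriers(
        self, ref_panel_two_signatures
    ):
        panel, truth = ref_panel_two_signatures
        trees = mask_and_refit(
            panel, truth, TreeFitParams(max_depth=3, complexity_penalty=5e-4), rounds=2
        )
        assert trees[0].snps_used == ["snp0020", "snp0028", "snp0036"]
        secondary = {"snp0008", "snp0012", "snp0044", "snp0050"}
        assert set(trees[1].snps_used) <= secondary
        best = predict_dosage(trees[1], panel).hap_p >= 0.5
        fn = int((~best & truth.x).sum())
        tp = int((best & truth.x).sum())
        assert fn > 0 and tp >= 20

    def test_exhausted_candidates_stop_early_with_warning(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(40, 2)).astype(np.int8)
        y = alleles[:, 0] == 1
        truth = FocalTruth(y=y, x=y)
        with pytest.warns(UserWarning):
            trees = mask_and_refit(_tiny_panel(alleles), truth,
                                   TreeFitParams(min_leaf_haplotypes=1), rounds=5)
        assert len(trees) < 5


class TestPrediction:
    def test_pure_leaf_dosages(self):
        alleles = np.array([[1, 0], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
        x = np.array([True, True, False, False])
        truth = FocalTruth(y=x, x=x)
        panel = _tiny_panel(alleles)
        tree = fit_haplotype_tree(panel, truth, TreeFitParams(min_leaf_haplotypes=1))
        res = predict_dosage(tree, panel)
        assert res.dosage["dosage"].tolist() == [2.0, 0.0]

    def test_leaf_probability_is_count_ratio(self, ref_panel):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        res = predict_dosage(tree, panel)
        founder_probs = res.hap_p[truth.y]
        assert np.allclose(founder_probs, 24 / 26)

    def test_missing_snp_in_target_errors(self, ref_panel):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        reduced = panel.subset_snps(np.arange(10))
        with pytest.raises(KeyError, match="snp0020"):
            predict_dosage(tree, reduced)

    def test_missing_allele_routed_by_majority(self, ref_panel):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        masked = HaplotypePanel(
            alleles=panel.alleles.copy(), snps=panel.snps,
            samples=list(panel.samples),
            missing=np.zeros_like(panel.alleles, dtype=bool),
        )
        masked.missing[0, :] = True
        res = predict_dosage(tree, masked)
        assert res.n_missing_routed > 0


class TestTreeR2:
    def test_self_comparison_is_one(self, ref_panel):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        own = predict_dosage(tree, panel).dosage["dosage"].to_numpy()
        assert tree_r2(tree, panel, own) == pytest.approx(1.0)

    def test_perfect_tag_truth_is_one(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(60, 5)).astype(np.int8)
        x = alleles[:, 2] == 1
        truth = FocalTruth(y=x, x=x)
        panel = _tiny_panel(alleles)
        tree = fit_haplotype_tree(panel, truth, TreeFitParams(min_leaf_haplotypes=1))
        assert tree_r2(tree, panel, truth.dosage()) == pytest.approx(1.0)

    def test_matches_covariance_formula(self, ref_panel, rng):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        pred = predict_dosage(tree, panel).dosage["dosage"].to_numpy()
        comp = rng.random(panel.n_individuals)
        r2 = tree_r2(tree, panel, comp)
        cov = np.mean(pred * comp) - pred.mean() * comp.mean()
        expect = cov ** 2 / (pred.var() * comp.var())
        assert r2 == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self, ref_panel):
        panel, truth = ref_panel
        tree = fit_haplotype_tree(panel, truth)
        with pytest.warns(UserWarning):
            assert tree_r2(tree, panel, np.ones(panel.n_individuals)) == 0.0


def test_json_roundtrip(ref_panel):
    panel, truth = ref_panel
    tree = fit_haplotype_tree(panel, truth)
    back = TreeModel.from_json(tree.to_json())
    assert back.snps_used == tree.snps_used
    assert predict_dosage(back, panel).dosage.equals(predict_dosage(tree, panel).dosage)
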
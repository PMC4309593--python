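"""Classification trees over phased haplotypes for founder identification.

Greedy binary recursive partitioning (CART with the Gini criterion) applied
to haplotype rows, with the focal-variant mutation indicator as the target.
Leaves store reference/mutation haplotype counts; a haplotype routed to a
leaf receives that leaf's mutation proportion as its carrier probability,
and an individual's dosage is the sum over its two haplotypes.

Determinism: ties between equally scoring splits are broken by lowest
genomic position.  A SNP is never reused on a root-to-leaf path.  Missing
alleles are routed down the branch that received the majority of the
training haplotypes at that node.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FocalTruth, HaplotypePanel


@dataclass
class TreeFitParams:
    candidate_snps: list[str] | None = None
    min_leaf_haplotypes: int = 2
    max_depth: int = 5
    complexity_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.min_leaf_haplotypes < 1:
            raise ValueError("min_leaf_haplotypes must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class TreeNode:
    """Internal node (split on one SNP allele) or leaf (class counts)."""

    n_ref: int
    n_mut: int
    snp_id: str | None = None
    split_allele: int = 1
    left: "TreeNode | None" = None   # haplotypes carrying split_allele
    right: "TreeNode | None" = None
    majority_branch: str = "right"   # routing for missing alleles

    @property
    def is_leaf(self) -> bool:
        return self.snp_id is None

    @property
    def p_mut(self) -> float:
        return self.n_mut / (self.n_ref + self.n_mut)

    def to_dict(self) -> dict:
        d = {"n_ref": self.n_ref, "n_mut": self.n_mut}
        if not self.is_leaf:
            d.update(
                snp_id=self.snp_id,
                split_allele=self.split_allele,
                majority_branch=self.majority_branch,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n_ref=d["n_ref"], n_mut=d["n_mut"])
        if "snp_id" in d:
            node.snp_id = d["snp_id"]
            node.split_allele = d["split_allele"]
            node.majority_branch = d["majority_branch"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeModel:
    """A fitted haplotype classification tree."""

    root: TreeNode
    snps_used: list[str] = field(default_factory=list)
    n_training: int = 0

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(
            {"root": self.root.to_dict(), "snps_used": self.snps_used,
             "n_training": self.n_training},
            indent=1,
        )
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "TreeModel":
        d = json.loads(s)
        return cls(
            root=TreeNode.from_dict(d["root"]),
            snps_used=d["snps_used"],
            n_training=d["n_training"],
        )


def _gini(n_mut: np.ndarray, n_tot: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_tot > 0, n_mut / np.maximum(n_tot, 1), 0.0)
    return 2.0 * p * (1.0 - p)


def fit_haplotype_tree(
    ref: HaplotypePanel, truth: FocalTruth, params: TreeFitParams | None = None
) -> TreeModel:
    """Fit a greedy Gini tree predicting the mutation from haplotype alleles."""
    params = params or TreeFitParams()
    x = np.asarray(truth.x, dtype=bool)
    if x.shape[0] != ref.n_haplotypes:
        raise ValueError("truth length must match haplotype count")
    if x.sum() == 0:
        raise ValueError("degenerate target: no mutation haplotypes in reference")

    if params.candidate_snps is None:
        cand_cols = np.arange(ref.n_snps)
    else:
        cand_cols = ref.snp_index(params.candidate_snps)
    alleles = ref.alleles
    miss = ref.missing_mask()
    pos = ref.snps["pos"].to_numpy()
    snp_ids = ref.snps["id"].to_numpy()
    used: set[str] = set()

    def build(rows: np.ndarray, depth: int, path_cols: frozenset) -> TreeNode:
        xr = x[rows]
        n_mut = int(xr.sum())
        n_tot = len(rows)
        node = TreeNode(n_ref=n_tot - n_mut, n_mut=n_mut)
        if (
            depth >= params.max_depth
            or n_mut == 0
            or n_mut == n_tot
            or n_tot < 2 * params.min_leaf_haplotypes
        ):
            return node

        cols = np.array([c for c in cand_cols if c not in path_cols])
        if len(cols) == 0:
            return node
        sub = alleles[np.ix_(rows, cols)] == 1
        msub = miss[np.ix_(rows, cols)]
        valid = ~msub
        n_left = (sub & valid).sum(axis=0)
        mut_left = (sub & valid & xr[:, None]).sum(axis=0)
        n_valid = valid.sum(axis=0)
        mut_valid = (valid & xr[:, None]).sum(axis=0)
        n_right = n_valid - n_left
        mut_right = mut_valid - mut_left

        parent = _gini(np.array([mut_valid], dtype=float), np.array([n_valid], dtype=float))[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            child = (
                n_left * _gini(mut_left.astype(float), n_left.astype(float))
                + n_right * _gini(mut_right.astype(float), n_right.astype(float))
            ) / np.maximum(n_valid, 1)
        gain = parent - child
        feasible = (
            (np.minimum(n_left, n_right) >= params.min_leaf_haplotypes)
            & (n_valid > 0)
        )
        gain = np.where(feasible, gain, -np.inf)
        threshold = max(params.complexity_penalty, 1e-12)
        if not np.any(gain > threshold):
            return node
        best_gain = gain.max()
        tied = np.flatnonzero(gain >= best_gain - 1e-12)
        best = tied[np.argmin(pos[cols[tied]])]
        col = cols[best]

        has = (alleles[rows, col] == 1) & ~miss[rows, col]
        lacks = (alleles[rows, col] == 0) & ~miss[rows, col]
        majority = "left" if has.sum() >= lacks.sum() else "right"
        mrows = miss[rows, col]
        left_rows = rows[has | (mrows if majority == "left" else np.zeros_like(mrows))]
        right_rows = rows[lacks | (mrows if majority == "right" else np.zeros_like(mrows))]

        node.snp_id = str(snp_ids[col])
        node.split_allele = 1
        node.majority_branch = majority
        used.add(node.snp_id)
        child_path = path_cols | {col}
        node.left = build(left_rows, depth + 1, child_path)
        node.right = build(right_rows, depth + 1, child_path)
        return node

    root = build(np.arange(ref.n_haplotypes), 0, frozenset())
    order = {s: i for i, s in enumerate(snp_ids)}
    return TreeModel(
        root=root,
        snps_used=sorted(used, key=lambda s: order[s]),
        n_training=ref.n_haplotypes,
    )


def mask_and_refit(
    ref: HaplotypePanel,
    truth: FocalTruth,
    params: TreeFitParams | None = None,
    rounds: int = 3,
) -> list[TreeModel]:
    """Refit the tree repeatedly, masking SNPs used by earlier rounds.

    Round k+1 excludes every SNP used by rounds 1..k, probing whether
    carrier prediction relies on a few sentinel SNPs.  Stops early with a
    warning once no informative SNPs remain.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    params = params or TreeFitParams()
    candidates = (
        list(params.candidate_snps)
        if params.candidate_snps is not None
        else list(ref.snps["id"])
    )
    trees: list[TreeModel] = []
    for _ in range(rounds):
        if not candidates:
            warnings.warn("candidate SNP set exhausted before requested rounds")
            break
        p = TreeFitParams(
            candidate_snps=candidates,
            min_leaf_haplotypes=params.min_leaf_haplotypes,
            max_depth=params.max_depth,
            complexity_penalty=params.complexity_penalty,
        )
        tree = fit_haplotype_tree(ref, truth, p)
        if not tree.snps_used:
            warnings.warn("no informative SNPs remain; stopping early")
            break
        trees.append(tree)
        candidates = [s for s in candidates if s not in tree.snps_used]
    return trees


@dataclass
class PredictionResult:
    """Per-haplotype carrier probabilities and per-individual dosages."""

    hap_p: np.ndarray
    dosage: pd.DataFrame  # sample_id, dosage, best_guess
    n_missing_routed: int = 0


def predict_dosage(tree: TreeModel, target: HaplotypePanel) -> PredictionResult:
    """Route target haplotypes through the tree and sum leaf probabilities.

    Best-guess carrier status rounds each haplotype at p_mut >= 0.5.
    """
    known = set(target.snps["id"])
    needed = [s for s in tree.snps_used if s not in known]
    if needed:
        raise KeyError(f"target panel lacks SNPs used by the tree: {needed}")
    col_of = {s: i for i, s in enumerate(target.snps["id"])}
    miss = target.missing_mask()
    p = np.empty(target.n_haplotypes)
    n_routed = 0
    for h in range(target.n_haplotypes):
        node = tree.root
        while not node.is_leaf:
            j = col_of[node.snp_id]
            if miss[h, j]:
                n_routed += 1
                node = node.left if node.majority_branch == "left" else node.right
            elif target.alleles[h, j] == node.split_allele:
                node = node.left
            else:
                node = node.right
        p[h] = node.p_mut
    dosage = p.reshape(-1, 2).sum(axis=1)
    best = (p.reshape(-1, 2) >= 0.5).sum(axis=1)
    df = pd.DataFrame(
        {"sample_id": target.samples, "dosage": dosage, "best_guess": best}
    )
    return PredictionResult(hap_p=p, dosage=df, n_missing_routed=n_routed)


def tree_r2(
    tree: TreeModel,
    panel: HaplotypePanel,
    comparison_dosage: np.ndarray,
) -> float:
    """Squared Pearson correlation of tree dosages with a comparison vector."""
    pred = predict_dosage(tree, panel).dosage["dosage"].to_numpy()
    comparison_dosage = np.asarray(comparison_dosage, dtype=float)
    if comparison_dosage.shape != pred.shape:
        raise ValueError("comparison vector length must equal individual count")
    if np.std(pred) == 0 or np.std(comparison_dosage) == 0:
        warnings.warn("zero variance in a dosage vector; r2 defined as 0")
        return 0.0
    r = np.corrcoef(pred, comparison_dosage)[0, 1]
    return float(r * r)
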
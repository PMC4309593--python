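"""Shared independent oracles used by several test modules."""

import numpy as np


def optimal_misclassification(alleles, x, max_depth, min_leaf=1):
    """Exhaustive-search oracle: minimum training misclassification over all
    depth-bounded binary trees splitting on single SNP alleles (dynamic
    programme over row subsets)."""

    def best(rows, depth):
        n_mut = int(x[rows].sum())
        err = min(n_mut, len(rows) - n_mut)
        if depth == 0 or err == 0:
            return err
        for j in range(alleles.shape[1]):
            has = alleles[rows, j] == 1
            nl, nr = int(has.sum()), int((~has).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            err = min(err, best(rows[has], depth - 1) + best(rows[~has], depth - 1))
        return err

    return best(np.arange(len(x)), max_depth)
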
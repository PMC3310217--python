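"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the tree-prior mass
function is obtained by exhaustive enumeration of valid parameter tuples,
and leaf marginals by numerical integration of the Dirichlet integrand.
"""

import numpy as np
from scipy import integrate


def enumerate_tree_prior(dataset, p_min, s_max):
    """Exact distribution of the leaf count k under the uniform prior over
    valid trees, by recursive enumeration of (structure, feature, rule)
    tuples.  Rules range over the globally observed values of each feature;
    a tree is valid when every leaf holds >= p_min records and it has at
    most s_max splits."""
    memo = {}

    def count(idx):
        key = idx.tobytes()
        if key in memo:
            return memo[key]
        out = {1: 1}
        for j in range(dataset.m):
            xj = dataset.X[idx, j]
            for rule in dataset.levels[j]:
                go_left = xj <= rule
                n_left = int(go_left.sum())
                if n_left < p_min or idx.size - n_left < p_min:
                    continue
                left = count(idx[go_left])
                right = count(idx[~go_left])
                for kl, vl in left.items():
                    for kr, vr in right.items():
                        k = kl + kr
                        if k - 1 <= s_max:
                            out[k] = out.get(k, 0) + vl * vr
        memo[key] = out
        return out

    counts = count(np.arange(dataset.n))
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def leaf_marginal_quad_2class(a, b):
    """Marginal likelihood of a two-class leaf with counts (a, b) under a
    uniform prior on the class-1 probability: numerical Beta integral."""
    val, _ = integrate.quad(lambda p: p**a * (1 - p) ** b, 0.0, 1.0)
    return val


def leaf_marginal_quad_3class(a, b, c):
    """Three-class analogue: 2-d integral over the probability simplex of
    p1^a p2^b (1-p1-p2)^c times the Dirichlet(1,1,1) density (= 2)."""
    val, _ = integrate.dblquad(
        lambda p2, p1: 2.0 * p1**a * p2**b * (1 - p1 - p2) ** c,
        0.0, 1.0, 0.0, lambda p1: 1 - p1,
    )
    return val


def total_variation(dist_a, dist_b):
    keys = set(dist_a) | set(dist_b)
    return 0.5 * sum(abs(dist_a.get(k, 0.0) - dist_b.get(k, 0.0)) for k in keys)
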
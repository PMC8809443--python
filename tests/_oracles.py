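"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning code path: likelihoods are
computed by exhaustive enumeration over internal-node state assignments,
and Wilcoxon exact p-values by enumeration of all sign vectors.
"""

import itertools

import numpy as np
from scipy import stats as sps


def brute_force_loglik(tree, tip_states, P_by_edge, pi):
    """Log-likelihood by summation over all internal-node state assignments.

    tip_states: (n_tips, n_sites) resolved integer states.
    P_by_edge[e]: transition matrix of the edge above node e.
    """
    n_states = len(pi)
    internals = [v for v in range(tree.n_nodes) if tree.children[v] and v != tree.root]
    n_sites = tip_states.shape[1]
    total = 0.0
    for site in range(n_sites):
        like = 0.0
        for root_state in range(n_states):
            for assign in itertools.product(range(n_states), repeat=len(internals)):
                state = {tree.root: root_state}
                state.update(dict(zip(internals, assign)))
                for t in range(tree.n_tips):
                    state[t] = int(tip_states[t, site])
                prob = pi[root_state]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    prob *= P_by_edge[v][state[tree.parent[v]], state[v]]
                like += prob
        total += np.log(like)
    return total


def wilcoxon_exact_enumeration(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Zero differences are dropped; midranks for ties.  p = min(1,
    2 * P(W+ <= min(W+, W-))) under random independent signs.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / 2**n)
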
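"""Independent oracles: exact finite-population chains and brute-force tree likelihoods.

These deliberately avoid the code paths they check: the fixation-probability
oracle solves the full discrete Markov chain by linear algebra, and the tree
likelihood oracle sums over all interior-node state assignments.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def exact_fixation_probability(two_N: int, w_mutant: float) -> float:
    """Absorption probability at 2N copies for a single new mutant.

    The haploid Wright-Fisher chain on {0..2N} mutant copies: from i copies
    the next generation is Binomial(2N, i w/(i w + 2N - i)).  Solved by a
    dense linear system over the transient states.
    """
    i = np.arange(two_N + 1)
    q = i * w_mutant / (i * w_mutant + (two_N - i))
    P = binom.pmf(np.arange(two_N + 1)[None, :], two_N, q[:, None])
    A = np.eye(two_N - 1) - P[1:-1, 1:-1]
    b = P[1:-1, -1]
    u = np.linalg.solve(A, b)
    return float(u[0])


def exact_conditional_fixation_time(two_N: int) -> float:
    """Mean generations to fixation of a single neutral mutant, given fixation."""
    i = np.arange(two_N + 1)
    q = i / two_N
    P = binom.pmf(np.arange(two_N + 1)[None, :], two_N, q[:, None])
    u = np.concatenate([[0.0], np.linalg.solve(
        np.eye(two_N - 1) - P[1:-1, 1:-1], P[1:-1, -1]), [1.0]])
    # conditioned chain: P*_ij = P_ij u_j / u_i on transient i
    Pt = P[1:-1, 1:-1] * u[1:-1][None, :] / u[1:-1][:, None]
    # also transitions straight to fixation keep the chain going one step
    t = np.linalg.solve(np.eye(two_N - 1) - Pt, np.ones(two_N - 1))
    return float(t[0])


def brute_force_loglik(tree, tip_states: dict[str, str], Q_P, pi) -> float:
    """Tree likelihood by explicit summation over interior-node states.

    ``Q_P`` maps a branch length to a 4x4 transition matrix.  Only feasible
    for a handful of tips; serves as the oracle for the pruning recursion.
    """
    state_space = range(4)
    labels = ("AB", "aB", "Ab", "ab")
    nodes = list(tree.postorder_node_iter())
    interior = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]

    def tip_allowed(leaf):
        s = tip_states[leaf.taxon.label]
        if s == "?":
            return list(state_space)
        return [labels.index(s)]

    total = 0.0
    import itertools

    for assignment in itertools.product(state_space, repeat=len(interior)):
        amap = {id(n): s for n, s in zip(interior, assignment)}
        prob = pi[amap[id(tree.seed_node)]]
        ok = True
        for n in interior:
            for child in n.child_nodes():
                length = child.edge.length or 0.0
                P = Q_P(length)
                if child.is_leaf():
                    p = sum(P[amap[id(n)], s] for s in tip_allowed(child))
                else:
                    p = P[amap[id(n)], amap[id(child)]]
                prob *= p
            if prob == 0.0:
                ok = False
                break
        if ok:
            total += prob
    return float(np.log(total))
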
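"""Phylogenetic substitution model over the four fixed haplotype states.

The instantaneous rate matrix Q is built from the substitution rates of one
:class:`~compsub.rates.RateSet` in one of two modes:

* ``arrow_rates`` — off-diagonal entries are the arrow rates of the four-state
  substitution chain themselves (r1 for fit -> deleterious neighbors, r2 for
  deleterious -> fit, r3/r4 for the direct AB <-> ab double moves).  This
  chain is time-reversible with respect to the stationary distribution pi.
* ``target_weighted`` — each arrow rate is additionally multiplied by the
  stationary probability of the target state (a GTR-style exchangeability
  weighting).  When r1 != r2 this weighting does not satisfy detailed
  balance with the symmetric pi; both modes are provided and the default is
  the balanced one.

Direct movement between the two deleterious states aB and Ab is structurally
zero.  Q is rescaled by u so that the expected substitution rate at
stationarity is 1, making branch lengths expected numbers of substitutions
per paired site.  The rates describe the origination process: a state change
is dated by the arrival of the copy destined to fix.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .model import Haplotype
from .rates import RateSet

__all__ = [
    "RateMatrix",
    "build_q",
    "transition_probabilities",
    "PairedSiteData",
    "pruning_loglik",
    "read_tree",
    "read_tip_states",
]

STATE_LABELS = ("AB", "aB", "Ab", "ab")
AMBIGUOUS = "?"


@dataclass
class RateMatrix:
    Q: np.ndarray
    u: float
    pi: np.ndarray
    mode: str


def build_q(rateset: RateSet, mode: str = "arrow_rates") -> RateMatrix:
    """Build the scaled 4x4 instantaneous rate matrix from a RateSet."""
    if mode not in ("arrow_rates", "target_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    r1, r2, r3, r4 = rateset.r1, rateset.r2, rateset.r3, rateset.r4
    pi = np.asarray(rateset.pi, dtype=float)
    for name, r in (("r1", r1), ("r2", r2), ("r3", r3), ("r4", r4)):
        if not np.isfinite(r) or r < 0:
            raise ValueError(f"rate {name}={r!r} must be finite and non-negative")

    AB, aB, Ab, ab = Haplotype.AB, Haplotype.aB, Haplotype.Ab, Haplotype.ab
    R = np.zeros((4, 4))
    R[AB, aB] = R[AB, Ab] = r1
    R[ab, aB] = R[ab, Ab] = r1
    R[aB, AB] = R[aB, ab] = r2
    R[Ab, AB] = R[Ab, ab] = r2
    R[AB, ab] = r3
    R[ab, AB] = r4
    # aB <-> Ab stays 0: the double move through (or around) a fitness peak
    if mode == "target_weighted":
        R = R * pi[None, :]
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    total_rate = -float(np.dot(pi, np.diag(R)))
    if total_rate <= 0:
        raise ValueError("all substitution rates are zero; cannot scale Q")
    u = 1.0 / total_rate
    return RateMatrix(Q=u * R, u=u, pi=pi, mode=mode)


def transition_probabilities(rate_matrix: RateMatrix, branch_length: float) -> np.ndarray:
    """P(t) = expm(Q t) for a branch length in expected substitutions per site."""
    if branch_length < 0:
        raise ValueError(f"branch length must be >= 0, got {branch_length!r}")
    return expm(rate_matrix.Q * branch_length)


# ---------------------------------------------------------------------------
# paired-site data and pruning likelihood
# ---------------------------------------------------------------------------

@dataclass
class PairedSiteData:
    """A newick tree with one haplotype state (or '?') per tip."""

    tree: dendropy.Tree
    tip_states: dict[str, str]

    def __post_init__(self) -> None:
        tree_tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        for tip, state in self.tip_states.items():
            if tip not in tree_tips:
                raise ValueError(f"tip {tip!r} in the data is missing from the tree")
            if state not in STATE_LABELS and state != AMBIGUOUS:
                raise ValueError(f"tip {tip!r} has unknown state {state!r}")
        missing = tree_tips - set(self.tip_states)
        if missing:
            raise ValueError(f"tree tips without a state entry: {sorted(missing)}")


def _tip_partial(state: str) -> np.ndarray:
    if state == AMBIGUOUS:
        return np.ones(4)
    v = np.zeros(4)
    v[STATE_LABELS.index(state)] = 1.0
    return v


def pruning_loglik(data: PairedSiteData, rate_matrix: RateMatrix) -> float:
    """Log-likelihood of the tip states by Felsenstein pruning.

    Partial likelihoods are propagated root-ward in postorder; the root is
    weighted by the stationary distribution.  Partials are rescaled per node
    to guard against underflow on deep trees; edges without a branch length
    (the root edge) are treated as length zero.
    """
    log_scale = 0.0
    partials: dict[int, np.ndarray] = {}
    for node in data.tree.postorder_node_iter():
        if node.is_leaf():
            partial = _tip_partial(data.tip_states[node.taxon.label])
        else:
            partial = np.ones(4)
            for child in node.child_nodes():
                length = child.edge.length if child.edge.length is not None else 0.0
                if length < 0:
                    raise ValueError(f"negative branch length {length!r}")
                P = transition_probabilities(rate_matrix, float(length))
                partial = partial * (P @ partials.pop(id(child)))
            m = partial.max()
            if m <= 0:
                return float("-inf")
            partial = partial / m
            log_scale += np.log(m)
        partials[id(node)] = partial
    root_partial = partials[id(data.tree.seed_node)]
    lik = float(np.dot(rate_matrix.pi, root_partial))
    if lik <= 0:
        return float("-inf")
    return float(np.log(lik) + log_scale)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_tree(path: str) -> dendropy.Tree:
    """Read a newick tree with branch lengths."""
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def read_tip_states(path: str) -> dict[str, str]:
    """Read a two-column TSV (tip_id, state in {AB, aB, Ab, ab, ?})."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"tip_id", "state"}.issubset(df.columns):
        raise ValueError("tip-state file must have columns tip_id and state")
    return dict(zip(df["tip_id"], df["state"]))
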
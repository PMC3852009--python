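"""The discrete-time jump chain embedded in the substitution process.

States are (AB, DEL, ab) where DEL pools the two deleterious intermediates
and ab is absorbing (matching the simulation stopping rule).  From AB the
chain moves directly to ab with probability beta and to DEL with 1 - beta;
from DEL it moves to AB or ab with probability 1/2 each.

The chain serves both as a model object and as an independent linear-algebra
oracle for the pathway split 2 beta/(1+beta) and for the geometric
distribution of reversions to the ancestral state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JumpChain",
    "build_chain",
    "absorption_pathway_split",
    "reversion_count_distribution",
    "reversion_joint_distribution",
    "reversion_mean",
    "sample_event_sequences",
]

STATES = ("AB", "DEL", "ab")
AB, DEL, ABS = 0, 1, 2


@dataclass(frozen=True)
class JumpChain:
    beta: float
    transition_matrix: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3 over (AB, DEL, ab)")
        if (T < -1e-15).any() or (T > 1 + 1e-15).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")


def build_chain(beta: float) -> JumpChain:
    """Jump chain for a given direct double-substitution probability beta."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta!r}")
    T = np.array(
        [
            [0.0, 1.0 - beta, beta],
            [0.5, 0.0, 0.5],
            [0.0, 0.0, 1.0],
        ]
    )
    return JumpChain(beta=beta, transition_matrix=T)


def absorption_pathway_split(chain: JumpChain) -> float:
    """P(the absorbing step into ab is the direct AB -> ab move | start at AB).

    Solved from the first-step equations of the chain (a 2x2 linear system),
    not from the closed form — so it can serve as an oracle for
    2 beta/(1 + beta).
    """
    T = chain.transition_matrix
    # d_i = P(enter ab directly from AB | currently at transient state i)
    # d = T_tt d + b, where b_AB = T[AB, ab] (the only direct entry).
    Ttt = T[:2, :2]
    b = np.array([T[AB, ABS], 0.0])
    d = np.linalg.solve(np.eye(2) - Ttt, b)
    return float(d[AB])


def reversion_joint_distribution(chain: JumpChain, k_max: int = 64) -> tuple[np.ndarray, float]:
    """Joint pmf over (number of returns to AB, final pathway type).

    Computed by stepwise path enumeration on the chain starting at AB:
    mass at AB with k returns either absorbs directly (Type 2), absorbs from
    DEL (Type 1), or returns to AB with k+1 returns.  Returns an array
    ``joint[k, type-1]`` for k in 0..k_max plus the unenumerated tail mass
    (paths with more than k_max returns).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    T = chain.transition_matrix
    joint = np.zeros((k_max + 1, 2))
    mass_ab_state = 1.0  # currently at AB having made k returns
    for k in range(k_max + 1):
        joint[k, 1] = mass_ab_state * T[AB, ABS]              # direct: Type 2
        m_del = mass_ab_state * T[AB, DEL]
        joint[k, 0] = m_del * T[DEL, ABS]                     # via DEL: Type 1
        mass_ab_state = m_del * T[DEL, AB]                    # one more return
    return joint, mass_ab_state


def reversion_count_distribution(chain: JumpChain, k_max: int = 64) -> np.ndarray:
    """Pmf of the number of returns to AB before absorption, k = 0..k_max."""
    joint, _ = reversion_joint_distribution(chain, k_max)
    return joint.sum(axis=1)


def reversion_mean(chain: JumpChain, k_max: int = 64) -> float:
    """Mean number of reversions, with the geometric tail beyond k_max folded in.

    Paths still unabsorbed after k_max returns contribute (k_max + 1) plus a
    geometric residue f/(1-f) with failure probability f = (1-beta)/2.
    """
    joint, tail = reversion_joint_distribution(chain, k_max)
    pmf = joint.sum(axis=1)
    k = np.arange(k_max + 1)
    mean = float(np.sum(k * pmf))
    if tail > 0.0:
        f = chain.transition_matrix[AB, DEL] * chain.transition_matrix[DEL, AB]
        mean += tail * ((k_max + 1) + f / (1.0 - f))
    return mean


def sample_event_sequences(
    chain: JumpChain, n: int, rng: np.random.Generator
) -> list[list[str]]:
    """Draw ``n`` state paths from AB to absorption, e.g. ['AB','DEL','AB','ab']."""
    T = chain.transition_matrix
    out = []
    for _ in range(n):
        path = ["AB"]
        state = AB
        while state != ABS:
            state = int(rng.choice(3, p=T[state]))
            path.append(STATES[state])
        out.append(path)
    return out
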
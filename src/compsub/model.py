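"""Shared parameter and state vocabulary for the two-locus compensatory model.

The model is the symmetric two-locus, two-allele haploid system: a population
of N diploid (2N haploid) individuals, alleles A/a at the first locus and B/b
at the second, bidirectional per-locus mutation rate mu, and genic selection
with fitnesses w(AB) = w(ab) = 1 and w(aB) = w(Ab) = 1 - s.  The two
single-mutant haplotypes are the deleterious intermediates of the fitness
valley separating the AB and ab peaks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Haplotype",
    "ModelParameters",
    "PopulationState",
    "make_parameters",
    "single_mutation_neighbors",
    "HAPLOTYPE_ORDER",
    "DELETERIOUS_MASK",
]


class Haplotype(enum.IntEnum):
    """The four haplotypes, in the canonical order (AB, aB, Ab, ab).

    The integer encoding doubles as a bit field: bit 0 is a mutant allele at
    the first locus (a), bit 1 a mutant allele at the second locus (b).
    Flipping one locus is an XOR with 1 or 2.
    """

    AB = 0
    aB = 1
    Ab = 2
    ab = 3

    @property
    def alleles(self) -> tuple[int, int]:
        """(first-locus, second-locus) mutant indicators."""
        return (self.value & 1, (self.value >> 1) & 1)

    @property
    def is_deleterious(self) -> bool:
        """True for the single-mutant intermediates aB and Ab (class X)."""
        a, b = self.alleles
        return a != b

    def fitness(self, s: float) -> float:
        return 1.0 - s if self.is_deleterious else 1.0


HAPLOTYPE_ORDER: tuple[Haplotype, ...] = (
    Haplotype.AB,
    Haplotype.aB,
    Haplotype.Ab,
    Haplotype.ab,
)

#: 1 for the deleterious class X = {aB, Ab}, 0 for the fit class Y = {AB, ab}.
DELETERIOUS_MASK = np.array([0, 1, 1, 0], dtype=np.int64)


def single_mutation_neighbors(h: Haplotype) -> set[Haplotype]:
    """Haplotypes reachable from ``h`` by a mutation at exactly one locus.

    The diagonal partner (the haplotype differing at both loci) is never a
    single-mutation neighbor; in particular aB and Ab are not neighbors.
    """
    h = Haplotype(h)
    return {Haplotype(h ^ 1), Haplotype(h ^ 2)}


@dataclass(frozen=True)
class ModelParameters:
    """Primitive parameters of the model.

    Parameters
    ----------
    two_N
        Haploid copy number 2N (the simulator operates on copies; the diploid
        population size is N = two_N / 2).  Must be an even integer >= 2.
    mu
        Mutation rate per locus, per copy, per generation (>= 0).
    s
        Selection coefficient against the deleterious intermediates,
        0 <= s < 1.
    rho
        Recombination rate per individual per generation (>= 0).

    The population-scaled quantities theta = 4 N mu, Ns, 2N rho and the
    renormalized advantage t = s / (1 - s) of a fit haplotype invading a
    deleterious background are derived properties, never stored.
    """

    two_N: int
    mu: float
    s: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if int(self.two_N) != self.two_N or self.two_N < 2 or self.two_N % 2:
            raise ValueError(
                f"two_N must be an even integer >= 2 (diploid N >= 1), got {self.two_N!r}"
            )
        object.__setattr__(self, "two_N", int(self.two_N))
        if self.mu < 0:
            raise ValueError(f"mutation rate mu must be >= 0, got {self.mu!r}")
        if not 0.0 <= self.s < 1.0:
            raise ValueError(f"selection coefficient s must satisfy 0 <= s < 1, got {self.s!r}")
        if self.rho < 0:
            raise ValueError(f"recombination rate rho must be >= 0, got {self.rho!r}")

    # -- derived, always recomputed ------------------------------------
    @property
    def N(self) -> float:
        """Diploid population size."""
        return self.two_N / 2

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 4 N mu (per locus)."""
        return 2.0 * self.two_N * self.mu

    @property
    def Ns(self) -> float:
        """Population-scaled selection intensity N s."""
        return self.N * self.s

    @property
    def t(self) -> float:
        """Selection advantage t = s/(1-s) of a fit haplotype on a 1-s background."""
        return self.s / (1.0 - self.s)

    @property
    def two_N_rho(self) -> float:
        """Population-scaled recombination rate 2N rho."""
        return self.two_N * self.rho

    def fitnesses(self) -> np.ndarray:
        """Fitness vector over the canonical haplotype order."""
        return np.where(DELETERIOUS_MASK == 1, 1.0 - self.s, 1.0)

    @classmethod
    def from_scaled(
        cls,
        two_N: int,
        theta: float,
        Ns: float,
        two_N_rho: float = 0.0,
    ) -> "ModelParameters":
        """Build parameters from the population-scaled quantities.

        mu = theta/(4N), s = Ns/N, rho = (2N rho)/(2N); round-trips exactly
        with direct construction.
        """
        if two_N < 2:
            raise ValueError(f"two_N must be >= 2, got {two_N!r}")
        if theta < 0:
            raise ValueError(f"theta must be >= 0, got {theta!r}")
        if Ns < 0:
            raise ValueError(f"Ns must be >= 0, got {Ns!r}")
        if two_N_rho < 0:
            raise ValueError(f"two_N_rho must be >= 0, got {two_N_rho!r}")
        N = two_N / 2
        s = Ns / N
        if s >= 1.0:
            raise ValueError(
                f"Ns={Ns!r} with two_N={two_N!r} implies s={s!r} >= 1; "
                "reduce Ns or increase two_N"
            )
        return cls(two_N=two_N, mu=theta / (2.0 * two_N), s=s, rho=two_N_rho / two_N)


def make_parameters(two_N: int, theta: float, Ns: float, two_N_rho: float = 0.0) -> ModelParameters:
    """Functional alias of :meth:`ModelParameters.from_scaled`."""
    return ModelParameters.from_scaled(two_N, theta, Ns, two_N_rho)


@dataclass
class PopulationState:
    """Haplotype counts of a population at one generation.

    ``counts`` follows the canonical order (AB, aB, Ab, ab) and always sums
    to the haploid copy number 2N.
    """

    counts: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,):
            raise ValueError("counts must be a length-4 vector (AB, aB, Ab, ab)")
        if (self.counts < 0).any():
            raise ValueError("haplotype counts must be non-negative")
        if self.generation < 0:
            raise ValueError("generation index must be non-negative")

    @property
    def two_N(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def monomorphic(cls, haplotype: Haplotype, two_N: int, generation: int = 0) -> "PopulationState":
        counts = np.zeros(4, dtype=np.int64)
        counts[int(haplotype)] = two_N
        return cls(counts=counts, generation=generation)

    def fixed_haplotype(self) -> Haplotype | None:
        """The haplotype the population is fixed for, or None if polymorphic."""
        j = int(np.argmax(self.counts))
        if self.counts[j] == self.counts.sum():
            return Haplotype(j)
        return None
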
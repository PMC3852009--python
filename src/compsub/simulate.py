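"""Forward Wright-Fisher simulation of the two-locus compensatory model.

Each generation applies, in order: Poisson(4N mu) mutation over copies chosen
without replacement, Poisson(2N rho) recombination events each crossing over
two copies chosen without replacement, and fitness-weighted multinomial
resampling of the 2N copies.  A replicate starts fixed for AB and ends when
ab fixes (or at the generation cap, flagged censored).  Every novel fixation
(a fixed haplotype different from the previously fixed one) is recorded; the
implicit AB fixation at generation 0 opens the event list.

Classification of a completed replicate: Type 2 if the fixed state
immediately before the ab fixation was AB, Type 1 if it was a deleterious
intermediate.  Reversions count the adjacent (intermediate-fixed ->
AB-fixed) pairs in the event list.

Generations in which the population is monomorphic and no mutation occurs
are identities of the process (recombination and resampling of identical
copies change nothing), so the loop advances through them in one geometric
draw; this is an exact shortcut, not an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import Haplotype, ModelParameters, PopulationState

__all__ = [
    "FixationEvent",
    "ReplicateRecord",
    "BatchSummary",
    "mutate",
    "recombine",
    "resample",
    "run_replicate",
    "run_batch",
]

DEFAULT_MAX_GENERATIONS = 50_000_000


@dataclass(frozen=True)
class FixationEvent:
    generation: int
    haplotype: Haplotype


@dataclass
class ReplicateRecord:
    """One simulated compensatory substitution event (AB -> ... -> ab)."""

    replicate_id: int
    seed: int
    events: list[FixationEvent]
    pathway_type: int | None  # 1, 2, or None when censored
    reversion_count: int
    total_generations: int
    final_path_generations: int
    censored: bool


# ---------------------------------------------------------------------------
# sub-steps (public wrappers operate on PopulationState; internals on counts)
# ---------------------------------------------------------------------------

def _apply_mutations(counts: np.ndarray, m: int, rng: np.random.Generator) -> None:
    """Mutate ``m`` distinct copies in place, locus chosen by fair coin each."""
    if m <= 0:
        return
    selected = rng.multivariate_hypergeometric(counts, m)
    for h in range(4):
        k = int(selected[h])
        if k == 0:
            continue
        n_locus1 = int(rng.binomial(k, 0.5))
        counts[h] -= k
        counts[h ^ 1] += n_locus1
        counts[h ^ 2] += k - n_locus1


def _apply_recombination(counts: np.ndarray, k_events: int, rng: np.random.Generator) -> None:
    """Apply ``k_events`` crossover events sequentially, in place."""
    for _ in range(k_events):
        pair = rng.multivariate_hypergeometric(counts, 2)
        idx = np.nonzero(pair)[0]
        if idx.size != 2:
            continue  # both copies carry the same haplotype: crossover is a no-op
        i, j = int(idx[0]), int(idx[1])
        # haplotype bits: bit0 = first-locus allele, bit1 = second-locus allele
        new1 = (i & 1) | (j & 2)
        new2 = (j & 1) | (i & 2)
        counts[i] -= 1
        counts[j] -= 1
        counts[new1] += 1
        counts[new2] += 1


def _resample(counts: np.ndarray, fitness: np.ndarray, two_N: int,
              rng: np.random.Generator) -> np.ndarray:
    w = counts * fitness
    return rng.multinomial(two_N, w / w.sum())


def mutate(state: PopulationState, params: ModelParameters,
           rng: np.random.Generator) -> PopulationState:
    """One round of mutation: m ~ Poisson(4N mu) copies (capped at 2N) flip one locus."""
    counts = state.counts.copy()
    m = min(int(rng.poisson(params.theta)), state.two_N)
    _apply_mutations(counts, m, rng)
    return PopulationState(counts=counts, generation=state.generation)


def recombine(state: PopulationState, params: ModelParameters,
              rng: np.random.Generator) -> PopulationState:
    """One round of recombination: Poisson(2N rho) sequential crossover events."""
    counts = state.counts.copy()
    k = int(rng.poisson(params.two_N_rho))
    _apply_recombination(counts, k, rng)
    return PopulationState(counts=counts, generation=state.generation)


def resample(state: PopulationState, params: ModelParameters,
             rng: np.random.Generator) -> PopulationState:
    """Wright-Fisher resampling with replacement, fitness-weighted."""
    counts = _resample(state.counts, params.fitnesses(), state.two_N, rng)
    return PopulationState(counts=counts, generation=state.generation + 1)


# ---------------------------------------------------------------------------
# compiled replicate kernel
#
# The per-generation law is identical to the PopulationState wrappers above;
# the kernel trades the numpy vector draws for scalar draws (sequential
# conditional binomials for the multinomial, sequential category-wise
# hypergeometrics for sampling copies without replacement) so the whole
# replicate runs at compiled speed.  At low theta a replicate spans millions
# of generations, almost all monomorphic with no mutation — those are exact
# identities of the process and are skipped with one geometric draw.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _poisson_positive_nb(lam: float) -> int:
    """Zero-truncated Poisson via inverse CDF on the residual mass."""
    p0 = math.exp(-lam)
    u = p0 + np.random.random() * (1.0 - p0)
    k = 0
    pk = p0
    cdf = p0
    while cdf < u and k < 10_000:
        k += 1
        pk *= lam / k
        cdf += pk
    if k < 1:
        k = 1
    return k


@njit(cache=True)
def _mutate_nb(counts: np.ndarray, m: int, two_N: int) -> None:
    """Mutate m distinct copies: category counts by sequential hypergeometric.

    Selection is from a snapshot of the pre-mutation counts so that a copy
    created by one mutation can never be hit by another in the same
    generation (sampling without replacement).
    """
    left = m
    tot = two_N
    sel = np.zeros(4, dtype=np.int64)
    for h in range(4):
        ch = counts[h]
        tot -= ch
        if left <= 0 or ch <= 0:
            sel[h] = 0
        elif tot <= 0:
            sel[h] = left
        else:
            sel[h] = np.random.hypergeometric(ch, tot, left)
        left -= sel[h]
    for h in range(4):
        if sel[h] > 0:
            k = sel[h]
            n1 = np.random.binomial(k, 0.5) if k > 1 else (1 if np.random.random() < 0.5 else 0)
            counts[h] -= k
            counts[h ^ 1] += n1
            counts[h ^ 2] += k - n1


@njit(cache=True)
def _pick_copy_nb(counts: np.ndarray, tot: int) -> int:
    r = np.random.randint(0, tot)
    c = 0
    for h in range(4):
        c += counts[h]
        if r < c:
            return h
    return 3


@njit(cache=True)
def _recombine_nb(counts: np.ndarray, k_events: int, two_N: int) -> None:
    for _ in range(k_events):
        i = _pick_copy_nb(counts, two_N)
        counts[i] -= 1
        j = _pick_copy_nb(counts, two_N - 1)
        counts[i] += 1
        if i != j:
            n1 = (i & 1) | (j & 2)
            n2 = (j & 1) | (i & 2)
            counts[i] -= 1
            counts[j] -= 1
            counts[n1] += 1
            counts[n2] += 1


@njit(cache=True)
def _resample_nb(counts: np.ndarray, s: float, two_N: int) -> None:
    """Fitness-weighted multinomial via sequential conditional binomials."""
    w0 = counts[0] * 1.0
    w1 = counts[1] * (1.0 - s)
    w2 = counts[2] * (1.0 - s)
    w3 = counts[3] * 1.0
    wsum = w0 + w1 + w2 + w3
    # two-haplotype fast path (the overwhelmingly common polymorphic state)
    n_nonzero = (1 if counts[0] else 0) + (1 if counts[1] else 0) \
        + (1 if counts[2] else 0) + (1 if counts[3] else 0)
    if n_nonzero <= 2:
        if n_nonzero == 1:
            return
        a = 0
        while counts[a] == 0:
            a += 1
        b = a + 1
        while counts[b] == 0:
            b += 1
        wa = counts[a] * (1.0 - s if (a == 1 or a == 2) else 1.0)
        na = np.random.binomial(two_N, wa / wsum)
        counts[a] = na
        counts[b] = two_N - na
        return
    rem = two_N
    # category 0
    p = w0 / wsum
    if p >= 1.0:
        n = rem
    elif p <= 0.0:
        n = 0
    else:
        n = np.random.binomial(rem, p)
    counts[0] = n
    rem -= n
    wsum -= w0
    # category 1
    if rem > 0 and wsum > 0.0:
        p = w1 / wsum
        if p >= 1.0:
            n = rem
        elif p <= 0.0:
            n = 0
        else:
            n = np.random.binomial(rem, p)
    else:
        n = 0
    counts[1] = n
    rem -= n
    wsum -= w1
    # category 2
    if rem > 0 and wsum > 0.0:
        p = w2 / wsum
        if p >= 1.0:
            n = rem
        elif p <= 0.0:
            n = 0
        else:
            n = np.random.binomial(rem, p)
    else:
        n = 0
    counts[2] = n
    rem -= n
    counts[3] = rem


@njit(cache=True)
def _replicate_kernel(two_N: int, theta: float, s: float, lam_rec: float,
                      seed: int, max_gen: int):
    np.random.seed(seed)
    counts = np.zeros(4, dtype=np.int64)
    counts[0] = two_N
    cap = 256
    ev_gen = np.empty(cap, dtype=np.int64)
    ev_hap = np.empty(cap, dtype=np.int64)
    ev_gen[0] = 0
    ev_hap[0] = 0
    n_ev = 1
    gen = 0
    last_fixed = 0
    censored = False
    p_no_mut = math.exp(-theta)
    p_no_rec = math.exp(-lam_rec) if lam_rec > 0.0 else 1.0

    while True:
        if counts[last_fixed] == two_N:
            # monomorphic: jump to the next generation with >= 1 mutation
            gap = np.random.geometric(1.0 - p_no_mut)
            if gen + gap > max_gen:
                gen = max_gen
                censored = True
                break
            gen += gap
            m = _poisson_positive_nb(theta)
            if m > two_N:
                m = two_N
            _mutate_nb(counts, m, two_N)
        else:
            if gen + 1 > max_gen:
                gen = max_gen
                censored = True
                break
            gen += 1
            if np.random.random() >= p_no_mut:
                m = _poisson_positive_nb(theta)
                if m > two_N:
                    m = two_N
                _mutate_nb(counts, m, two_N)
        if lam_rec > 0.0 and (
            (counts[0] > 0 and counts[3] > 0) or (counts[1] > 0 and counts[2] > 0)
        ):
            # a crossover only changes the state when the two copies differ
            # at both loci; without a coexisting diagonal pair every event
            # is a no-op and the draws can be skipped outright
            if np.random.random() >= p_no_rec:
                k = _poisson_positive_nb(lam_rec)
                _recombine_nb(counts, k, two_N)
        _resample_nb(counts, s, two_N)
        j = 0
        mx = counts[0]
        for h in range(1, 4):
            if counts[h] > mx:
                mx = counts[h]
                j = h
        if mx == two_N and j != last_fixed:
            if n_ev == cap:
                new_gen = np.empty(cap * 2, dtype=np.int64)
                new_hap = np.empty(cap * 2, dtype=np.int64)
                new_gen[:cap] = ev_gen
                new_hap[:cap] = ev_hap
                ev_gen = new_gen
                ev_hap = new_hap
                cap *= 2
            ev_gen[n_ev] = gen
            ev_hap[n_ev] = j
            n_ev += 1
            last_fixed = j
            if j == 3:
                break

    return ev_gen[:n_ev], ev_hap[:n_ev], gen, censored


# ---------------------------------------------------------------------------
# replicate loop
# ---------------------------------------------------------------------------

def _classify(events: list[FixationEvent], censored: bool,
              end_generation: int) -> tuple[int | None, int, int, int]:
    """(pathway_type, reversion_count, total_generations, final_path_generations)."""
    reversions = 0
    for prev, nxt in zip(events, events[1:]):
        if prev.haplotype.is_deleterious and nxt.haplotype == Haplotype.AB:
            reversions += 1
    last_ab_gen = max(e.generation for e in events if e.haplotype == Haplotype.AB)
    total = end_generation
    final_path = end_generation - last_ab_gen
    if censored:
        return None, reversions, total, final_path
    pathway = 2 if events[-2].haplotype == Haplotype.AB else 1
    return pathway, reversions, total, final_path


def run_replicate(
    params: ModelParameters,
    seed: int,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
    replicate_id: int = 0,
) -> ReplicateRecord:
    """Simulate one compensatory event; identical (params, seed) replays bit-identically."""
    if params.mu <= 0:
        raise ValueError("run_replicate requires mu > 0 (theta = 0 never terminates)")
    ev_gen, ev_hap, gen, censored = _replicate_kernel(
        params.two_N, params.theta, params.s, params.two_N_rho,
        int(seed) & 0xFFFFFFFF, int(max_generations),
    )
    events = [FixationEvent(int(g), Haplotype(int(h))) for g, h in zip(ev_gen, ev_hap)]
    pathway, reversions, total, final_path = _classify(events, censored, int(gen))
    return ReplicateRecord(
        replicate_id=replicate_id,
        seed=seed,
        events=events,
        pathway_type=pathway,
        reversion_count=reversions,
        total_generations=total,
        final_path_generations=final_path,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

@dataclass
class BatchSummary:
    n_replicates: int
    n_type1: int
    n_type2: int
    n_censored: int
    mean_total_generations: float
    sd_total_generations: float
    mean_final_path_generations: float
    sd_final_path_generations: float
    mean_reversions: float
    sd_reversions: float
    base_seed: int


def summarize(records: list[ReplicateRecord], base_seed: int = 0) -> BatchSummary:
    done = [r for r in records if not r.censored]
    total = np.array([r.total_generations for r in done], dtype=float)
    final = np.array([r.final_path_generations for r in done], dtype=float)
    rev = np.array([r.reversion_count for r in done], dtype=float)

    def _mean(a): return float(a.mean()) if a.size else float("nan")
    def _sd(a): return float(a.std(ddof=1)) if a.size > 1 else float("nan")

    return BatchSummary(
        n_replicates=len(records),
        n_type1=sum(1 for r in done if r.pathway_type == 1),
        n_type2=sum(1 for r in done if r.pathway_type == 2),
        n_censored=len(records) - len(done),
        mean_total_generations=_mean(total),
        sd_total_generations=_sd(total),
        mean_final_path_generations=_mean(final),
        sd_final_path_generations=_sd(final),
        mean_reversions=_mean(rev),
        sd_reversions=_sd(rev),
        base_seed=base_seed,
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> np.ndarray:
    """Deterministic per-replicate 32-bit seeds derived from the base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n_replicates, np.uint32)


def run_batch(
    params: ModelParameters,
    n_replicates: int,
    base_seed: int,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
    progress: callable = None,
) -> tuple[list[ReplicateRecord], BatchSummary]:
    """Run ``n_replicates`` independent replicates with seeds derived from ``base_seed``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(base_seed, n_replicates)
    records = []
    for i in range(n_replicates):
        records.append(
            run_replicate(params, int(seeds[i]), max_generations=max_generations,
                          replicate_id=i)
        )
        if progress is not None and (i + 1) % 1000 == 0:
            progress(i + 1, n_replicates)
    return records, summarize(records, base_seed=base_seed)
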
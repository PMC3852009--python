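"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from compsub.jumpchain import build_chain, sample_event_sequences
from compsub.model import Haplotype
from compsub.simulate import FixationEvent, ReplicateRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def record_from_sequence(
    seq: list[Haplotype],
    replicate_id: int = 0,
    censored: bool = False,
    generations: list[int] | None = None,
    final_path: int | None = None,
) -> ReplicateRecord:
    """Build a ReplicateRecord from an explicit fixation sequence.

    ``seq`` starts with the implicit generation-0 AB state.  Generations
    default to 0, 1, 2, ...; classification counters are derived from the
    sequence the same way the simulator derives them.
    """
    if generations is None:
        generations = list(range(len(seq)))
    events = [FixationEvent(g, h) for g, h in zip(generations, seq)]
    reversions = sum(
        1 for a, b in zip(seq, seq[1:])
        if a.is_deleterious and b == Haplotype.AB
    )
    total = generations[-1]
    last_ab = max(g for g, h in zip(generations, seq) if h == Haplotype.AB)
    if censored:
        pathway = None
    else:
        pathway = 2 if seq[-2] == Haplotype.AB else 1
    fp = final_path if final_path is not None else total - last_ab
    return ReplicateRecord(
        replicate_id=replicate_id,
        seed=0,
        events=events,
        pathway_type=pathway,
        reversion_count=reversions,
        total_generations=total,
        final_path_generations=fp,
        censored=censored,
    )


def jump_chain_records(beta: float, n: int, seed: int) -> list[ReplicateRecord]:
    """Synthetic replicate records drawn from the jump chain at known beta.

    DEL states are realized as aB; generations are consecutive integers,
    which suffices for every counting estimator.
    """
    rng = np.random.default_rng(seed)
    chain = build_chain(beta)
    records = []
    for i, path in enumerate(sample_event_sequences(chain, n, rng)):
        seq = [Haplotype.AB if s == "AB" else (Haplotype.aB if s == "DEL" else Haplotype.ab)
               for s in path]
        records.append(record_from_sequence(seq, replicate_id=i))
    return records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130)
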
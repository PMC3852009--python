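# Methods

## The model

`compsub` studies compensatory substitution: the fixation of two mutations
that are individually deleterious but jointly neutral.  The model is the
symmetric two-locus, two-allele haploid system.  A population of N diploid
(2N haploid) individuals carries one of four haplotypes — AB, aB, Ab, ab —
with genic fitnesses w(AB) = w(ab) = 1 and w(aB) = w(Ab) = 1 − s, where
0 ≤ s < 1 penalizes the single-mutant intermediates.  Mutation is
bidirectional and uniform at rate µ per locus per copy per generation;
recombination occurs at rate ρ per individual per generation.  The
population-scaled parameters are θ = 4Nµ, Ns and 2Nρ.

A population fixed for AB can reach fixation for ab along two pathways:

* **Type 1** — a deleterious intermediate (aB or Ab) fixes first, and the
  compensating mutation fixes afterwards;
* **Type 2** — the last fixed state before ab is AB itself: both loci were
  simultaneously polymorphic during the final transit, and the intermediate
  never fixed.

## Substitution rates between fixed states

The four fixed states form a continuous-time Markov chain over novel
fixation events, with three distinct arrow rates (origination rates — a
transition is dated by the arrival of the copy destined to fix, not by the
completion of its sweep):

* `r1 = 2Nµ (1 − e^{2s})/(1 − e^{4Ns})` — a fit fixed state loses to one
  particular deleterious intermediate (mutational input 2Nµ times the
  diffusion fixation probability of a copy with penalty s);
* `r2 = 2Nµ (1 − e^{−2t})/(1 − e^{−4Nt})`, `t = s/(1−s)` — a deleterious
  fixed state loses to one particular fit state (t is the selective
  advantage of a fit copy once mean fitness is renormalized to the
  deleterious background);
* `r3 = r4` — the direct double substitution AB → ab (and ab → AB).

Both fixation kernels switch to the neutral limit `1/(2N)` when the scaled
selection argument falls below 1e−8, avoiding the 0/0 of the exponential
ratio.  Against the exact 201-state discrete chain (2N = 200) the diffusion
kernels are accurate to ~0.3% at s = 0.005 and ~1.5% at s = 0.01; the
deleterious kernel degrades to ~18% by s = 0.03 because the target
probability decays exponentially in 4Ns while the diffusion error terms do
not.  This is a property of the closed form itself, not of its
implementation; the exact-chain comparison in the test suite documents it.

## The direct double-substitution rate

Pooling the two intermediates at frequency x (and the two fit haplotypes at
1 − x) reduces the interior dynamics to one dimension.  At mutation-
selection-drift balance x follows Wright's density

    φ(x) = C e^{−4Nsx} x^{2θ−1} (1−x)^{2θ−1},

where the exponent 2θ − 1 reflects that either locus can create or destroy
an intermediate.  The orientation of the exponential (selection *depleting*
the deleterious class) is the one consistent with the fixation kernels and
with simulation; the opposite orientation is available as `sign="printed"`.

The total rate at which successful ab haplotypes arise is

    α = 2Nµ ∫ x · p_ab(x) · φ(x) dx,
    p_ab(x) = p_y / (2N y′),   y′ = (1−x) + 1/(2N),

with `p_y = (1 − e^{−4Nt y′})/(1 − e^{−4Nt})` the fixation probability of
the fit class after the new mutant enters.  Writing p_y with t (the same
scaling as r2) makes p_ab(1) collapse exactly to the beneficial fixation
kernel, so the flux subtraction below cancels cleanly at the endpoint; the
raw-penalty form (s in place of t, as the paired-parameter expansion is
usually written) is available as `kernel="literal"` and differs at O(s²).

α marginalizes over *all* configurations in which ab can arise, so it
contains both the flux that passes through a fixed intermediate and the
direct flux.  With fixed-state occupancies π (from flow balance,
π_X/π_Y = r1/r2, split evenly within each class by symmetry):

    r3 = (α − (π_aB + π_Ab) r2) / (π_AB + π_ab).

The denominator is the *combined* fit-class occupancy.  The derivation of α
considers a population lacking the ab haplotype, so its fit-class weight is
concentrated on the AB-fixed state; equivalently, under the unconditioned
stationary process the same successful-ab originations occur at equal rate
from both fit fixed states (from ab-fixed they produce no state change) and
α counts both.  Dividing by π_AB alone double-counts and yields a direct
rate about twice what forward simulation produces; dividing by π_Y
reproduces the simulated direct-transition rate to within binomial error
across the grid.  The per-π_AB form is retained as
`r3_denominator="per_state"` for comparison.

From r1 and r3 follow

* the direct double-substitution probability β = r3 / (2r1 + r3);
* the pathway split P(Type 2) = 2β/(1+β), from the embedded jump chain;
* the expected number of reversions to AB, (1−β)/(1+β) — the number of
  returns is geometric on {0, 1, ...} with success probability (1+β)/2.

**Known limitation (neutral corner).**  At s = 0 the subtraction cancels
exactly (α = µ/2 = π_X r2) and the theory predicts β = 0, but the simulator
genuinely produces direct double substitutions at an O(θ) rate through
simultaneous polymorphism at both loci (≈1% of AB-departures at θ = 0.01,
≈10% at θ = 0.1).  The analytic β is therefore a slight underestimate near
Ns = 0, visible as the only systematic theory–simulation discrepancy in the
test grid.  At the opposite extreme (θ ≈ 1) the weak-mutation assumptions
behind α degrade, as expected.

**Small negative residues.**  At very small θ the subtraction can come out
slightly negative (up to ~1e−3 of α) because the flow-balance occupancy
ratio r1/r2 and the density's boundary-mass ratio e^{−4Ns} differ at O(s),
while the true r3 there is O(µ²).  Residues within 1e−2·α are clamped to
zero with a warning; anything larger raises, signalling genuine breakdown.

## Quadrature

The density's endpoint singularities (2θ − 1 ≤ −0.998 at θ = 0.001) are
absorbed into a Gauss–Jacobi rule with weight x^{2θ−1}(1−x)^{2θ−1} on
(0, 1); integrands are only ever evaluated at interior nodes.  The default
is 64 nodes with a doubling check (64 → 128) asserted below 1e−8 relative
on the normalizer and mean.  More nodes do not help: the rule already
integrates the smooth exponential factor to ~1e−9 by n = 32, while the
near-singular Jacobi weights themselves become noisier as n grows (128 → 256
doubling deltas reach ~3e−8 at θ = 0.001).  Moderate n with a doubling
check is the accurate regime.

## The jump chain

Collapsing the two intermediates into one state DEL gives the discrete
chain over (AB, DEL, ab) with AB → ab probability β, AB → DEL probability
1 − β, and DEL → AB = DEL → ab = 1/2; ab is absorbing to match the
simulation stopping rule.  The module solves the absorption-pathway split
by first-step linear equations and enumerates the reversion distribution by
stepwise dynamic programming — both serve as independent oracles for the
closed forms 2β/(1+β) and (1−β)/(1+β), and the enumeration conditional on
the final pathway verifies that the reversion distribution is
pathway-independent.

## The simulator

Forward Wright–Fisher sampling of 2N haploid copies, per generation:

1. **Mutation**: m ~ Poisson(4Nµ), capped at 2N; m distinct copies are
   chosen uniformly without replacement (a copy created by one mutation can
   never be hit again in the same generation); each flips one locus chosen
   by fair coin.
2. **Recombination**: k ~ Poisson(2Nρ) sequential events; each picks two
   distinct copies uniformly (equivalent to frequency-proportional haplotype
   choice without replacement) and exchanges second-locus alleles.
3. **Resampling**: the next generation is one multinomial draw of size 2N
   with probabilities proportional to count × fitness.

A replicate starts fixed for AB and ends when ab fixes, or censors at the
generation cap (default 5e7).  Fixation is checked once per generation
after resampling; every novel fixation is recorded, with the initial AB
counting as a fixation at generation 0 for classification and final-path
timing.

Two exact shortcuts keep replicates tractable at low θ (where a replicate
spans ~1e7 generations): (i) monomorphic generations with no mutation are
identities of the process and are skipped with a single geometric draw;
(ii) a crossover only changes the state when the two chosen copies differ
at both loci, so recombination draws are skipped whenever no diagonal pair
(AB with ab, or aB with Ab) coexists.  Neither changes the law of the
process.  The inner loop is compiled (numba); the multinomial is realized
as sequential conditional binomials and the without-replacement selection
as sequential category-wise hypergeometrics.  Identical (parameters, seed)
replays are bit-identical; batch replicate seeds derive from the base seed
through a seed sequence.

State is the 4-vector of haplotype counts rather than an individual list —
exchangeability makes the two equivalent and counts are orders of magnitude
faster.

## Estimators

β̂ pools, over all completed replicates and every AB-fixed position in each
event list (the generation-0 AB included), the fraction of AB-departures
whose next novel fixation is ab.  P̂(Type 2) is the fraction of completed
replicates whose final stepping stone was AB.  Proportions carry 95% Wilson
score intervals, which remain usable at the grid extremes where estimates
sit near 0 or 1.  Censored replicates are excluded from every estimator and
counted separately.

The path-time comparison takes, per replicate, the generations from the
last entry into AB until the entry into ab, and forms the two-sample
statistic z = (m₁ − m₂)/√(s_p²(1/n₁ + 1/n₂)) with the standard pooled
variance s_p² (Welch available as an option).  Under equal expected
durations z is approximately standard normal; with fewer than two
replicates of either type the result is flagged undefined rather than
raising.

## The phylogenetic substitution model

The arrow rates define a 4×4 instantaneous rate matrix Q over
(AB, aB, Ab, ab) with the structural zero aB ↔ Ab (direct movement between
the two intermediates would require crossing a fitness peak).  Two
constructions are shipped:

* `arrow_rates` (default): off-diagonals are the arrow rates themselves.
  This chain satisfies detailed balance with π (π_AB r1 = π_aB r2 follows
  from the flow-balance definition of π), so it is time-reversible and π is
  provably its stationary distribution.
* `target_weighted`: each rate additionally multiplied by the stationary
  probability of the target state (GTR-style).  With r1 ≠ r2 this weighting
  is not balanced with respect to the symmetric π; its empirical stationary
  distribution (left null vector) is exposed for comparison rather than a
  choice being silently made.

Q is rescaled so that the expected substitution rate at stationarity,
−Σ π_i q_ii, equals 1: branch lengths are expected substitutions per paired
site.  Transition probabilities use a dense scaling-and-squaring matrix
exponential (no reversibility assumption, since the weighted mode may be
non-reversible).  Tip-state likelihoods on a newick tree use Felsenstein
pruning with the root weighted by π, per-node rescaling against underflow,
and `?` as full ambiguity.  Like the rates it is built from, the model
describes the origination process.

## Synthetic data and what the tests show

The simulator is the data generator; no external data exist.  Default study
conditions follow the simulation design: 2N = 200, θ ∈ {0.001, 0.01, 0.1,
1.0}, Ns ∈ [0, 3], 2Nρ ∈ {0, 5}.  The acceptance grid runs θ ∈ {0.01, 0.1}
× Ns ∈ {0, 1, 2, 3} at 500 replicates per cell with recombination arms at
θ = 0.01, Ns ∈ {2, 3} — problem sizes chosen so the whole suite completes
on a single CPU while leaving binomial intervals tight enough to detect the
factor-two errors the cross-checks are designed to catch.  θ = 0.001 cells
are exercised analytically and through the rate-matrix grid but not
simulated at scale (waiting times there reach ~1e7 generations per
replicate and estimates censor heavily).

What passing tests do show: internal consistency of the closed forms, exact
agreement of the jump-chain oracles, and statistical agreement of theory
with the model's own forward simulation.  What they cannot show: anything
about real sequence data — the model assumes two biallelic loci, symmetric
mutation, equal intermediate fitnesses, a single panmictic population of
constant size, and genic (haploid) selection.

## Numerical and design choices

* Internal canonical population size is the haploid copy number 2N; the
  diploid N of the closed forms is derived from it.  Haplotype order is
  (AB, aB, Ab, ab) everywhere.
* Mutation draws above 2N are capped (selection without replacement cannot
  exceed the copy number); the event has negligible probability at all
  study conditions.
* Recombination events apply sequentially within a generation, each
  sampling from the state left by the previous event.
* The resampling detail is the standard fitness-weighted multinomial; the
  single-sentence description of the scheme fully determines the marginal
  law.
* Configuration is a flat key-value file (TOML syntax) with CLI flag
  overrides; every artifact embeds the resolved configuration, base seed
  and version, and contains no timestamps, so reruns are byte-identical.
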
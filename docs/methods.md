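# Methods

## Model

`trapsim` simulates a diploid, panmictic Wright–Fisher population of
constant size N with non-overlapping generations and no sexes. The state of
an individual is the pair of its haplotypes, each a sparse set of occupied
insertion sites; every base pair of the genome is a potential site
(0-based, half-open coordinates). One TE family is modelled; sequence
content, insertion orientation and escape mutants are out of scope.

The generation cycle (in order): fitness-proportional draw of two parents
per offspring (independent draws with replacement, so selfing is possible);
one recombinant gamete per parent; excisions, then novel insertions, on
gametes of active parents; zygote formation; cluster counting; fitness.

**Silencing (trap model).** An individual is *silenced* iff it carries at
least one insertion in a piRNA cluster on either haplotype — a dominant,
trans-acting effect. Activity is a property of the diploid parent and is
applied to its gametes: gametes of silenced parents receive neither novel
insertions nor excisions. Silencing does not affect transmission;
cluster copies are inherited and recombine like any other copy.

**Transposition.** Gametes of active parents gain Poisson(u·k) novel copies,
where k is the gamete's copy number excluding reference-region copies.
Because a zygote's two gametes carry n/2 copies on average, the expected
per-diploid gain is u·n — rate u per copy per generation. A Poisson law
(rather than per-copy Bernoulli) permits multiple events per copy at u = 1.
Insertion sites are uniform over the genome; a draw landing on a site
already occupied on the same gamete is discarded, not resampled, so the
realized rate falls slightly below u in small or crowded genomes.

**Excision.** Each genomic copy on an active parent's gamete is removed
independently with probability v. Cluster copies cannot be excised (active
parents have none by definition) and reference copies are exempt.

**Recombination.** Per chromosome and meiosis, the crossover count is
Poisson with mean `recomb_rate [cM/Mb] × length [Mb] / 100` without
interference; breakpoint positions are uniform; chromosomes assort
independently (uniform starting haplotype). The batch engine counts, for
each copy, all breakpoints of the meiosis up to the copy's position;
breakpoints on earlier chromosomes contribute a constant parity per
(meiosis, chromosome) which the independent uniform phase draw absorbs, so
the sampled transmission law is identical to the per-chromosome definition.

**Fitness.** `w = max(0, 1 − x·nᵗ)`; the linear model is t = 1. n counts
all copies except reference-region copies; the cluster-neutral variant also
exempts cluster copies. Individuals with w = 0 never reproduce; a run stops
as "extinct" when mean fitness drops below 0.1, and as "lost" when no copy
remains.

**Reference regions** mirror the clusters at the opposite chromosome ends.
Their insertions are inert (no silencing, no transposition source, no
fitness effect, no excision) but segregate and recombine normally; they are
the neutral control against which selection on cluster insertions is
measured.

## Default architecture and parameters

Five 10-Mb chromosomes at 4 cM/Mb with one 300-kb cluster at each
chromosome start (3% of the 50-Mb genome); u = 0.1, v = 0, x = 0
(neutral), N = 1,000, ten seeded insertions, each at a distinct uniform
site on one uniform haplotype (frequency 1/2N). Predefined scenarios cover
the architecture contrasts: `flamenco` (one 1-Mb trap, crossovers off) vs
`germline` (five 200-kb traps) on five 2-Mb chromosomes, their recombining
variants, and the 200-Mb `dmel_germline` (3.5% clusters) / `dmel_somatic`
(one non-recombining 300-kb cluster, 0.15%) settings. Because
recombination rates are per-chromosome, "non-recombining trap" scenarios
set the crossover rate of the affected chromosomes to zero; independent
assortment between chromosomes always remains, which is the dominant
source of trap recombination in the distributed-cluster scenarios.

## Phase annotation and outcomes

Phases are detected on recorded generations, per replicate: the shotgun
phase starts at the first generation with ≥ 99% of individuals carrying a
cluster insertion; the inactive phase at the first fixed cluster site
(which implies the 99% condition). Phase stability is the standard
deviation of the per-generation population-mean copy number within the
phase. Outcomes at an evaluation generation are `lost`, `extinct`,
`three_phase` (a cluster insertion fixed), or `tsc_balance`. TSC balance —
the equilibrium where segregating cluster insertions and negative selection
jointly hold copy numbers at a plateau — requires: TEs persist; no fixed
cluster site; fewer than 99% of individuals protected; segregating cluster
sites present; a stable copy number (|OLS slope| over the trailing 20% of
records below 10⁻³ copies/generation by default); and persistent activity,
mean novel insertions per individual over the same window ≥ 0.01. The
activity condition is part of the balance's definition (the TE "remains
persistently active") and excludes drift-only remnants of the seeded
insertions, which are otherwise flat, unfixed and unprotected. For scaled
scans (N = 250) the slope tolerance is raised to 10⁻², matching the larger
sampling noise of the plateau; both tolerances are arguments of
`classify_outcome` / `parameter_space_scan`. Parameter-space scans draw u
and x log-uniformly (matching the log-scaled axes on which the quadrants
N·u ≷ 1, N·x ≷ 1 are defined) and start from 1,000 seeded insertions. Scan
ranges must respect the horizon: a point only yields an interpretable
outcome if its invasion can complete within the simulated generations, so
the lower bound of u is chosen with u_min × generations ≈ several
e-foldings of copy-number growth (a slower point evaluated mid-growth
looks spuriously like a stable plateau). Even so, knife-edge points with
u ≈ x hover quasi-stably for longer than any finite horizon, which is why
TSC outcomes concentrate in — rather than being strictly confined to — the
N·u > 1, N·x > 1 quadrant.

Plateau abundance of a replicate (used for the abundance quantiles of the
Drosophila-scale scenarios) is the population-mean copy number at its last
recorded generation, halved for haploid units.

## Randomness and reproducibility

One master seed; replicate k runs on `SeedSequence(seed, spawn_key=(k,))`,
so any replicate is reproducible in isolation and replicate sets are
order-independent. All draws of a replicate pass through its single
generator. Identical seeds give bit-identical trajectories; run manifests
echo every parameter and the per-replicate spawn keys.

## What the synthetic conditions do and do not show

The simulated genome is a caricature: uniform recombination, equal-sized
chromosomes, one TE family, no insertion bias, no paramutation, no arms
race. Passing tests show that the population-genetic machinery (drift,
linkage, trap silencing, selection) behaves as the model prescribes — not
that real piRNA clusters behave this way. Two quantitative caveats are
documented from our own validation runs: (i) establishment of an invasion
is lower than the branching-process formula pe = 1 − (1 − 2u)ⁿ predicts,
because copies co-transmit within individuals (a transposed copy enters
the same gamete as its source) and because nascent lineages can be trapped
while still small — e.g. ~0.14 observed vs 0.18 predicted at u = 0.01
and ~0.72 vs 0.89 at u = 0.1 (the formula is an upper bound); (ii) the
onset of the shotgun phase arrives at ~3.5 cluster insertions per diploid
under the default setting, slightly below the four-to-six range quoted for
the reference implementation of this model class.

## Problem sizes in the test suite

The statistical tests run at sizes chosen for single-CPU desk use: 30
established replicates for the u = 0.1 slowdown statistics (N = 1,000, 500
generations); 1,000 replicates for establishment counts; phase-stability
and fixation-endpoint checks at N = 100 (fixation scales with 2Ne);
architecture contrasts with 30 replicates per setup; selection contrasts
with 50 replicates at N = 250 over 250 generations; TSC scans with 20 + 12
log-uniform points at N = 250 over 3,000 generations; Drosophila-scale
ordinal contrast on a proportionally scaled 20-Mb genome. Quantile-level
reproduction of the full 200-Mb Drosophila abundance intervals is not a
desk-scale computation and only the ordinal somatic ≫ germline contrast is
asserted.
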
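import numpy as np
import pytest
from scipy import stats

from trapsim import (
    FitnessModel,
    Haplotype,
    Individual,
    Population,
    SimulationParameters,
    apply_excision,
    apply_transposition,
    build_architecture,
    make_gamete,
    run_invasion,
    run_replicates,
    rng_for_replicate,
    step_generation,
)
from trapsim.engine import ExtinctionError, select_parent_index

NEUTRAL = FitnessModel()


def flat_pop(haps, arch, model=NEUTRAL):
    return Population.from_haplotype_lists(
        [np.asarray(h, dtype=np.int64) for h in haps]
    ).refresh(arch, model)


# ---------------------------------------------------------------------------
# parent selection
# ---------------------------------------------------------------------------


class TestSelectParent:
    def test_uniform_when_fitness_equal(self, default_arch, rng):
        pop = flat_pop([[ ], []] * 4, default_arch)  # 4 empty individuals, w=1
        draws = np.array([select_parent_index(pop, rng) for _ in range(20_000)])
        observed = np.bincount(draws, minlength=4)
        chi2, p = stats.chisquare(observed)
        assert p > 1e-4

    def test_fitness_proportional_ratio(self, default_arch, rng):
        pop = flat_pop([[], []] * 2, default_arch)
        pop.fitness = np.array([0.9, 0.3])
        n = 20_000
        draws = np.array([select_parent_index(pop, rng) for _ in range(n)])
        frac = np.mean(draws == 0)
        sd = np.sqrt(0.75 * 0.25 / n)
        assert abs(frac - 0.75) < 4 * sd

    def test_zero_fitness_never_selected(self, default_arch, rng):
        pop = flat_pop([[], []] * 3, default_arch)
        pop.fitness = np.array([1.0, 0.0, 1.0])
        draws = [select_parent_index(pop, rng) for _ in range(2000)]
        assert 1 not in draws

    def test_all_zero_fitness_raises(self, default_arch, rng):
        pop = flat_pop([[], []], default_arch)
        pop.fitness = np.array([0.0])
        with pytest.raises(ExtinctionError):
            select_parent_index(pop, rng)


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------


class TestMakeGamete:
    def test_no_recombination_transmits_whole_chromosomes(self, rng):
        arch = build_architecture([1, 1], [0, 0], [0, 0], [])
        h1 = np.array([10, 20, 30, 1_000_005], dtype=np.int64)
        h2 = np.array([55, 1_000_050, 1_000_060], dtype=np.int64)
        ind = Individual.from_haplotypes(Haplotype(h1), Haplotype(h2), arch)
        per_chrom = {
            0: (frozenset({10, 20, 30}), frozenset({55})),
            1: (frozenset({1_000_005}), frozenset({1_000_050, 1_000_060})),
        }
        for _ in range(50):
            g = set(make_gamete(ind, arch, rng).sites.tolist())
            for c, (a, b) in per_chrom.items():
                got = frozenset(s for s in g if c * 1_000_000 <= s < (c + 1) * 1_000_000)
                assert got in (a, b)

    def test_recombinant_fraction_matches_poisson_map(self, rng):
        # 10 Mb at 4 cM/Mb: lambda=0.4; markers at the two chromosome ends
        # recombine with frequency (1 - exp(-2*lambda)) / 2
        arch = build_architecture([10], [4], [0], [])
        ind = Individual.from_haplotypes(
            Haplotype(np.array([0], dtype=np.int64)),
            Haplotype(np.array([9_999_999], dtype=np.int64)),
            arch,
        )
        n = 6000
        rec = 0
        for _ in range(n):
            g = make_gamete(ind, arch, rng)
            if len(g) != 1:  # both or neither marker: parental types carry one
                rec += 1
        expected = (1 - np.exp(-2 * 0.4)) / 2
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 4 * sd

    def test_independent_assortment_across_chromosomes(self, rng):
        arch = build_architecture([1, 1], [0, 0], [0, 0], [])
        ind = Individual.from_haplotypes(
            Haplotype(np.array([5, 1_000_005], dtype=np.int64)),
            Haplotype(np.empty(0, np.int64)),
            arch,
        )
        n = 4000
        both = sum(len(make_gamete(ind, arch, rng)) == 2 for _ in range(n))
        sd = np.sqrt(0.25 * 0.75 / n)
        assert abs(both / n - 0.25) < 4 * sd


class TestExcision:
    def test_identity_cases(self, default_arch, rng):
        g = Haplotype(np.array([400_000, 500_000], dtype=np.int64))
        assert apply_excision(g, True, 0.0, rng) is g
        assert apply_excision(g, False, 1.0, rng) is g

    def test_full_excision_empties_gamete(self, default_arch, rng):
        g = Haplotype(np.array([400_000, 500_000], dtype=np.int64))
        assert len(apply_excision(g, True, 1.0, rng, default_arch)) == 0

    def test_binomial_removal_fraction(self, rng):
        arch = build_architecture([100], [0], [0], [])
        sites = rng.choice(arch.total_bp, size=50_000, replace=False)
        g = Haplotype(np.sort(sites))
        out = apply_excision(g, True, 0.1, rng, arch)
        removed = len(g) - len(out)
        sd = np.sqrt(len(g) * 0.1 * 0.9)
        assert abs(removed - 0.1 * len(g)) < 4 * sd

    def test_reference_sites_protected(self, rng):
        arch = build_architecture([1], [0], [0], [1000])
        ref = np.arange(999_000, 1_000_000, dtype=np.int64)
        g = Haplotype(ref)
        out = apply_excision(g, True, 1.0, rng, arch)
        assert len(out) == len(ref)


class TestTransposition:
    def test_silenced_parent_never_gains(self, default_arch, rng):
        g = Haplotype(np.arange(400_000, 400_020, dtype=np.int64))
        for _ in range(50):
            _, n_new = apply_transposition(g, False, 1.0, default_arch, rng)
            assert n_new == 0

    def test_poisson_mean(self, default_arch, rng):
        g = Haplotype(np.arange(400_000, 400_010, dtype=np.int64))  # k=10
        n = 3000
        gained = [apply_transposition(g, True, 0.1, default_arch, rng)[1] for _ in range(n)]
        sd = np.sqrt(1.0 / n)
        assert abs(np.mean(gained) - 1.0) < 4 * sd

    def test_saturated_single_site_genome(self, rng):
        arch = build_architecture([1e-6], [0], [0], [])
        g = Haplotype(np.array([0], dtype=np.int64))
        for _ in range(30):
            out, n_new = apply_transposition(g, True, 1.0, arch, rng)
            assert n_new == 0 and len(out) == 1

    def test_reference_copies_not_a_source(self, rng):
        arch = build_architecture([1], [0], [0], [500])
        g = Haplotype(
            np.concatenate([np.arange(10, dtype=np.int64), np.arange(999_500, 999_990, 50, dtype=np.int64)])
        )  # 10 genomic + 10 reference copies
        n = 3000
        gained = [apply_transposition(g, True, 0.1, arch, rng)[1] for _ in range(n)]
        # mean u*k with k=10 (reference excluded), not 20
        assert abs(np.mean(gained) - 1.0) < 4 * np.sqrt(1.0 / n)


# ---------------------------------------------------------------------------
# generation step invariants
# ---------------------------------------------------------------------------


class TestStepGeneration:
    def test_no_forces_keeps_fixed_site_fixed(self, default_arch, rng):
        params = SimulationParameters(u=0, v=0, x=0, N=50)
        pop = flat_pop([[400_000]] * 100, default_arch)
        for _ in range(20):
            pop, novel = step_generation(pop, default_arch, params, rng)
            assert novel == 0
        assert pop.total_copies == 100
        assert all(len(pop.haplotype(h)) == 1 for h in range(100))

    def test_copy_number_accounting_exact(self, default_arch, rng):
        params = SimulationParameters(u=0.2, v=0.05, N=100, n_seed=0)
        from trapsim import init_population

        pop = init_population(default_arch, 100, 80, rng).refresh(
            default_arch, NEUTRAL
        )
        for _ in range(30):
            pop, novel, detail = step_generation(
                pop, default_arch, params, rng, return_detail=True
            )
            assert detail["inherited"] - detail["excised"] + detail["novel"] == detail["final"]
            assert detail["final"] == pop.total_copies
            assert novel == detail["novel"]
            if pop.total_copies == 0:
                break

    def test_dominant_silencing_blocks_all_activity(self, default_arch, rng):
        # one step from all-carrier parents: silenced parents contribute no
        # novel insertions and no excisions
        haps = []
        for i in range(60):
            haps.append(np.array([5 + i], dtype=np.int64))  # cluster site
            haps.append(np.array([400_000 + i], dtype=np.int64))
        pop = flat_pop(haps, default_arch)
        params = SimulationParameters(u=1.0, v=0.5, N=60)
        seen_sites = set(np.unique(pop.sites).tolist())
        child, novel = step_generation(pop, default_arch, params, rng)
        assert novel == 0
        assert set(np.unique(child.sites).tolist()) <= seen_sites

    def test_homozygous_carriers_silence_forever(self, default_arch, rng):
        # cluster insertions on both haplotypes: every gamete carries one,
        # so every descendant is a carrier and activity never resumes
        haps = []
        for i in range(40):
            haps.append(np.array([5 + i, 400_000 + i], dtype=np.int64))
            haps.append(np.array([10_000 + i], dtype=np.int64))  # still cluster
        pop = flat_pop(haps, default_arch)
        params = SimulationParameters(u=1.0, v=0.5, N=40)
        seen_sites = set(np.unique(pop.sites).tolist())
        for _ in range(10):
            pop, novel = step_generation(pop, default_arch, params, rng)
            assert novel == 0
            assert set(np.unique(pop.sites).tolist()) <= seen_sites

    def test_neutral_fixation_probability_matches_initial_frequency(self, rng):
        # Wright-Fisher check: a neutral site at frequency p fixes with
        # probability ~p
        arch = build_architecture([1], [0], [0], [])
        N, p = 30, 0.2
        params = SimulationParameters(u=0, v=0, x=0, N=N)
        reps, fixed = 2000, 0
        for _ in range(reps):
            haps = [np.array([77], dtype=np.int64)] * int(2 * N * p) + [
                np.empty(0, np.int64)
            ] * int(2 * N * (1 - p))
            order = rng.permutation(2 * N)
            pop = flat_pop([haps[i] for i in order], arch)
            for _ in range(1500):
                if pop.total_copies in (0, 2 * N):
                    break
                pop, _ = step_generation(pop, arch, params, rng)
            fixed += pop.total_copies == 2 * N
        sd = np.sqrt(p * (1 - p) / reps)
        assert abs(fixed / reps - p) < 4 * sd

    def test_clusterless_neutral_growth_rate(self, default_arch, rng):
        # without clusters the mean copy number grows ~(1+u) per generation
        arch = build_architecture([10] * 5, [4] * 5, [0] * 5, [])
        u = 0.2
        params = SimulationParameters(u=u, N=200, n_seed=0)
        from trapsim import init_population

        pop = init_population(arch, 200, 400, rng).refresh(arch, NEUTRAL)
        log_copies = [np.log(pop.total_copies)]
        for _ in range(25):
            pop, _ = step_generation(pop, arch, params, rng)
            log_copies.append(np.log(pop.total_copies))
        slope = np.polyfit(np.arange(len(log_copies)), log_copies, 1)[0]
        assert abs(slope - np.log(1 + u)) < 0.02


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------


class TestRunInvasion:
    def test_strong_selection_loses_te(self, default_arch):
        params = SimulationParameters(
            u=0.01, x=0.2, model="linear", N=100, n_seed=10, generations=400, seed=2
        )
        traj = run_invasion(default_arch, params)
        assert traj.status == "lost"
        assert traj.records[-1].mean_copies == 0

    def test_unchecked_deleterious_invasion_goes_extinct(self):
        arch = build_architecture([10] * 5, [4] * 5, [0] * 5, [])  # no traps
        params = SimulationParameters(
            u=1.0, x=0.002, model="linear", N=100, n_seed=50, generations=400, seed=3
        )
        traj = run_invasion(arch, params)
        assert traj.status == "extinct"
        assert traj.records[-1].mean_fitness < 0.1

    def test_records_are_consecutive_and_start_at_zero(self, default_arch):
        params = SimulationParameters(u=0.1, N=50, n_seed=10, generations=40, seed=4)
        traj = run_invasion(default_arch, params)
        gens = [r.generation for r in traj.records]
        assert gens[0] == 0
        assert gens == sorted(gens)


class TestReplicates:
    def test_same_seed_bit_identical(self, default_arch):
        params = SimulationParameters(u=0.1, N=60, n_seed=10, generations=60, seed=9, replicates=3)
        a = run_replicates(default_arch, params)
        b = run_replicates(default_arch, params)
        for ta, tb in zip(a, b):
            assert ta.status == tb.status
            assert ta.to_frame().equals(tb.to_frame())

    def test_different_seed_differs(self, default_arch):
        p1 = SimulationParameters(u=0.1, N=60, n_seed=10, generations=60, seed=9, replicates=1)
        p2 = p1.evolve(seed=10)
        a = run_replicates(default_arch, p1)[0]
        b = run_replicates(default_arch, p2)[0]
        assert not a.to_frame().equals(b.to_frame())

    def test_replicate_reproducible_in_isolation(self, default_arch):
        params = SimulationParameters(u=0.1, N=60, n_seed=10, generations=60, seed=9, replicates=3)
        batch = run_replicates(default_arch, params)
        solo = run_invasion(
            default_arch, params, rng_for_replicate(9, 2), replicate=2
        )
        assert batch[2].to_frame().equals(solo.to_frame())

    def test_established_only_filter(self, default_arch):
        params = SimulationParameters(u=0.05, N=100, n_seed=2, generations=150, seed=8, replicates=5)
        trajs = run_replicates(default_arch, params, established_only=True)
        assert len(trajs) == 5
        assert all(t.established for t in trajs)
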
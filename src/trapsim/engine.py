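"""The per-generation cycle and whole-invasion runs.

Each generation executes, in order: (1) fitness-proportional choice of two
parents per offspring, (2) one recombinant gamete per parent, (3) excisions
on gametes of active parents, (4) novel insertions on gametes of active
parents, (5) zygote formation, (6) cluster counting, (7) fitness, (8)
optional record emission.

"Active" is a property of the diploid parent: a parent carrying at least one
piRNA-cluster insertion (on either haplotype) is silenced, and its gametes
receive neither excisions nor novel insertions. Reference-region copies are
inherited and recombine normally but never transpose, are never excised and
never affect fitness.

:func:`step_generation` is a vectorized batch implementation operating on the
flat population arrays; :func:`select_parent`, :func:`make_gamete`,
:func:`apply_excision` and :func:`apply_transposition` are the equivalent
single-individual operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import GenomeArchitecture, SiteClass
from .fitness import FitnessModel
from .params import SimulationParameters
from .population import Haplotype, Individual, Population, init_population

__all__ = [
    "SimulationParameters",
    "GenerationRecord",
    "Trajectory",
    "ExtinctionError",
    "step_generation",
    "select_parent",
    "make_gamete",
    "apply_excision",
    "apply_transposition",
    "run_invasion",
    "run_replicates",
    "rng_for_replicate",
    "fitness_model_of",
]


class ExtinctionError(RuntimeError):
    """Raised when every individual has fitness zero."""


def fitness_model_of(params: SimulationParameters) -> FitnessModel:
    return FitnessModel(kind=params.model, x=params.x, t=params.t)


# ---------------------------------------------------------------------------
# single-individual reference operations
# ---------------------------------------------------------------------------


def select_parent_index(pop: Population, rng: np.random.Generator) -> int:
    """Index of an individual drawn with probability proportional to fitness."""
    w = pop.fitness
    tw = float(w.sum())
    if tw <= 0:
        raise ExtinctionError("total fitness is zero")
    return int(rng.choice(pop.N, p=w / tw))


def select_parent(pop: Population, rng: np.random.Generator) -> Individual:
    return pop.individual(select_parent_index(pop, rng))


def make_gamete(
    ind: Individual, arch: GenomeArchitecture, rng: np.random.Generator
) -> Haplotype:
    """One recombinant gamete.

    Per chromosome: the starting haplotype is uniform (independent
    assortment), the crossover count is Poisson with mean
    ``recomb_rate * length_Mb / 100`` (no interference) and breakpoint
    positions are uniform within the chromosome.
    """
    out: list[np.ndarray] = []
    for c in range(arch.n_chromosomes):
        lo = int(arch.chrom_starts[c])
        hi = int(arch.chrom_ends[c])
        phase = int(rng.integers(0, 2))
        k = int(rng.poisson(arch.crossover_lambda[c]))
        bps = (
            np.sort(rng.integers(lo + 1, hi, size=k, dtype=np.int64))
            if k
            else np.empty(0, np.int64)
        )
        for h, hap in enumerate((ind.hap1, ind.hap2)):
            s = hap.sites[(hap.sites >= lo) & (hap.sites < hi)]
            if s.size:
                cur = (phase + np.searchsorted(bps, s, side="right")) & 1
                out.append(s[cur == h])
    sites = np.concatenate(out) if out else np.empty(0, np.int64)
    return Haplotype(sites)


def apply_excision(
    gamete: Haplotype,
    parent_active: bool,
    v: float,
    rng: np.random.Generator,
    arch: GenomeArchitecture | None = None,
) -> Haplotype:
    """Remove each copy independently with probability ``v`` if the parent is
    active; silenced parents contribute unchanged gametes. Reference-region
    copies are never excised (pass ``arch`` to classify them); cluster copies
    cannot occur on an active parent's gamete by definition."""
    if not parent_active or v <= 0 or not len(gamete):
        return gamete
    removable = np.ones(len(gamete), dtype=bool)
    if arch is not None:
        removable = arch.classify_sites(gamete.sites) == SiteClass.GENOMIC
    drop = removable & (rng.random(len(gamete)) < v)
    return Haplotype(gamete.sites[~drop])


def apply_transposition(
    gamete: Haplotype,
    parent_active: bool,
    u: float,
    arch: GenomeArchitecture,
    rng: np.random.Generator,
) -> tuple[Haplotype, int]:
    """Add novel insertions to the gamete of an active parent.

    The insertion count is Poisson with mean ``u * k`` where ``k`` counts the
    gamete's copies excluding reference-region sites. New sites are uniform
    genome-wide; a draw landing on an occupied site of this gamete is
    discarded (not resampled). Silenced parents gain nothing.
    """
    if not parent_active or u <= 0:
        return gamete, 0
    k = len(gamete)
    if k and arch.total_ref_bp:
        k = int(np.count_nonzero(arch.classify_sites(gamete.sites) != SiteClass.REFERENCE))
    n_draw = int(rng.poisson(u * k))
    if n_draw == 0:
        return gamete, 0
    draws = rng.integers(0, arch.total_bp, size=n_draw, dtype=np.int64)
    new_sites = np.unique(draws)
    if len(gamete):
        new_sites = new_sites[~np.isin(new_sites, gamete.sites)]
    if not new_sites.size:
        return gamete, 0
    return Haplotype(np.concatenate([gamete.sites, new_sites])), int(new_sites.size)


# ---------------------------------------------------------------------------
# vectorized generation step
# ---------------------------------------------------------------------------


def step_generation(
    pop: Population,
    arch: GenomeArchitecture,
    params: SimulationParameters,
    rng: np.random.Generator,
    return_detail: bool = False,
):
    """Produce the next generation; returns ``(population, novel_insertions)``.

    ``novel_insertions`` counts insertions actually added at the
    transposition step (collision draws excluded). With
    ``return_detail=True`` a bookkeeping dict (inherited / excised / novel
    copy counts) is appended to the return tuple.
    """
    N = pop.N
    two_n = 2 * N
    G = arch.total_bp
    model = fitness_model_of(params)

    w = pop.fitness
    tw = float(w.sum())
    if tw <= 0:
        raise ExtinctionError("total fitness is zero")
    # meiosis m (m = 2*offspring + hap_slot) draws parent independently
    parents = rng.choice(N, size=two_n, p=w / tw)

    counts = pop.n_total[parents]
    T = int(counts.sum())
    act_m = pop.n_cluster[parents] == 0

    if T:
        # gather every copy of every chosen parent, tagged by meiosis
        starts = pop.indptr[2 * parents]
        mid = pop.indptr[2 * parents + 1]
        offs = np.repeat(np.cumsum(counts) - counts, counts)
        idx = np.arange(T, dtype=np.int64) - offs + np.repeat(starts, counts)
        g_sites = pop.sites[idx]
        g_cls = pop.site_class[idx]
        g_chrom = pop.site_chrom[idx]
        g_hap = (idx >= np.repeat(mid, counts)).astype(np.int8)
        g_m = np.repeat(np.arange(two_n, dtype=np.int64), counts)

        # recombination: random chromosome phase + Poisson crossovers
        nchrom = arch.n_chromosomes
        phases = rng.integers(0, 2, size=(two_n, nchrom), dtype=np.int8)
        if arch.crossover_lambda.any():
            ks = rng.poisson(arch.crossover_lambda, size=(two_n, nchrom))
            K = int(ks.sum())
        else:
            K = 0
        if K:
            reps = ks.ravel()
            c_rep = np.repeat(np.tile(np.arange(nchrom), two_n), reps)
            m_rep = np.repeat(np.arange(two_n, dtype=np.int64), ks.sum(axis=1))
            bp_pos = rng.integers(
                arch.chrom_starts[c_rep] + 1, arch.chrom_ends[c_rep], dtype=np.int64
            )
            bp_keys = np.sort(m_rep * G + bp_pos)
            # counts all breakpoints of the meiosis up to the site; breakpoints
            # on earlier chromosomes add a constant parity per (meiosis,
            # chromosome), which the independent uniform phase draw absorbs
            cnt = np.searchsorted(bp_keys, g_m * G + g_sites, side="right")
            cur = (phases[g_m, g_chrom] + cnt) & 1
        else:
            cur = phases[g_m, g_chrom]
        transmitted = cur == g_hap

        # excision on gametes of active parents (genomic copies only)
        keep = transmitted
        n_excised = 0
        if params.v > 0:
            cand = transmitted & act_m[g_m] & (g_cls == SiteClass.GENOMIC)
            drop = cand & (rng.random(T) < params.v)
            n_excised = int(np.count_nonzero(drop))
            keep = transmitted & ~drop

        t_sites = g_sites[keep]
        t_m = g_m[keep]
        t_cls = g_cls[keep]
        t_counts = np.bincount(t_m, minlength=two_n)
        n_inherited = int(np.count_nonzero(transmitted))
    else:
        t_sites = np.empty(0, np.int64)
        t_m = np.empty(0, np.int64)
        t_cls = np.empty(0, np.int8)
        t_counts = np.zeros(two_n, dtype=np.int64)
        n_inherited = 0
        n_excised = 0

    # transposition: Poisson(u * non-reference copies) per active gamete
    novel = 0
    new_sites = np.empty(0, np.int64)
    i_counts = np.zeros(two_n, dtype=np.int64)
    if params.u > 0 and T:
        k_src = np.bincount(t_m[t_cls != SiteClass.REFERENCE], minlength=two_n)
        n_new = rng.poisson(params.u * k_src * act_m)
        I = int(n_new.sum())
        if I:
            new_m = np.repeat(np.arange(two_n, dtype=np.int64), n_new)
            draws = rng.integers(0, G, size=I, dtype=np.int64)
            ukeys = np.unique(new_m * G + draws)  # dedupe within gamete
            # discard draws on sites already occupied on the same gamete
            key_t = t_m * G + t_sites
            pos = np.searchsorted(ukeys, key_t)
            inb = pos < ukeys.size
            hit = np.zeros(key_t.size, dtype=bool)
            hit[inb] = ukeys[pos[inb]] == key_t[inb]
            occupied = np.zeros(ukeys.size, dtype=bool)
            occupied[pos[hit]] = True
            keep_keys = ukeys[~occupied]
            novel = int(keep_keys.size)
            if novel:
                new_m_f = keep_keys // G
                new_sites = keep_keys - new_m_f * G
                i_counts = np.bincount(new_m_f, minlength=two_n)

    # zygotes: haplotype m of offspring m//2 = transmitted + novel copies
    hap_counts = t_counts + i_counts
    indptr = np.concatenate(([0], np.cumsum(hap_counts)))
    child_sites = np.empty(int(hap_counts.sum()), dtype=np.int64)
    if t_sites.size:
        within = np.arange(t_sites.size, dtype=np.int64) - np.repeat(
            np.cumsum(t_counts) - t_counts, t_counts
        )
        child_sites[np.repeat(indptr[:-1], t_counts) + within] = t_sites
    if novel:
        within = np.arange(new_sites.size, dtype=np.int64) - np.repeat(
            np.cumsum(i_counts) - i_counts, i_counts
        )
        child_sites[np.repeat(indptr[:-1] + t_counts, i_counts) + within] = new_sites

    child = Population(child_sites, indptr, N=N, generation=pop.generation + 1)
    child.refresh(arch, model)
    if return_detail:
        detail = {
            "inherited": n_inherited,
            "excised": n_excised,
            "novel": novel,
            "final": child.total_copies,
        }
        return child, novel, detail
    return child, novel


# ---------------------------------------------------------------------------
# records and trajectories
# ---------------------------------------------------------------------------


@dataclass
class GenerationRecord:
    """Per-generation population summary (means over all N individuals)."""

    generation: int
    mean_copies: float
    mean_cluster: float
    mean_reference: float
    fraction_with_cluster: float
    fixed_cluster_sites: int
    seg_sites_genomic: int
    seg_sites_cluster: int
    seg_sites_reference: int
    mean_fitness: float
    novel_per_individual: float

    COLUMNS = (
        "generation",
        "mean_copies",
        "mean_cluster",
        "mean_reference",
        "fraction_with_cluster",
        "fixed_cluster_sites",
        "seg_sites_genomic",
        "seg_sites_cluster",
        "seg_sites_reference",
        "mean_fitness",
        "novel_per_individual",
    )

    def as_tuple(self):
        return tuple(getattr(self, c) for c in self.COLUMNS)


def summarize(pop: Population, novel: int = 0) -> GenerationRecord:
    """Build a :class:`GenerationRecord` from a refreshed population."""
    two_n = 2 * pop.N
    seg = {SiteClass.GENOMIC: 0, SiteClass.CLUSTER: 0, SiteClass.REFERENCE: 0}
    fixed_cluster = 0
    for cls in seg:
        sub = pop.sites[pop.site_class == cls]
        if sub.size:
            _, cnt = np.unique(sub, return_counts=True)
            n_fixed = int(np.count_nonzero(cnt == two_n))
            seg[cls] = int(cnt.size) - n_fixed
            if cls == SiteClass.CLUSTER:
                fixed_cluster = n_fixed
    return GenerationRecord(
        generation=pop.generation,
        mean_copies=float(pop.n_total.mean()),
        mean_cluster=float(pop.n_cluster.mean()),
        mean_reference=float(pop.n_reference.mean()),
        fraction_with_cluster=float(np.mean(pop.n_cluster > 0)),
        fixed_cluster_sites=fixed_cluster,
        seg_sites_genomic=seg[SiteClass.GENOMIC],
        seg_sites_cluster=seg[SiteClass.CLUSTER],
        seg_sites_reference=seg[SiteClass.REFERENCE],
        mean_fitness=float(pop.fitness.mean()),
        novel_per_individual=novel / pop.N,
    )


@dataclass
class Trajectory:
    """One replicate invasion: parameters, per-generation records, outcome."""

    params: SimulationParameters
    records: list[GenerationRecord]
    status: str  # completed | lost | extinct
    replicate: int = 0
    final_population: Population | None = None

    @property
    def established(self) -> bool:
        """TE copies survived to the end of the run."""
        return self.status != "lost" and self.records[-1].mean_copies > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.as_tuple() for r in self.records], columns=GenerationRecord.COLUMNS
        )

    def record_at(self, generation: int) -> GenerationRecord | None:
        """Record for an exact generation, or None if not recorded/reached."""
        for r in self.records:
            if r.generation == generation:
                return r
        return None


def default_record_schedule(gen: int) -> bool:
    """Record every generation up to 1,000, every 10th afterwards."""
    return gen <= 1000 or gen % 10 == 0


def run_invasion(
    arch: GenomeArchitecture,
    params: SimulationParameters,
    rng: np.random.Generator | None = None,
    *,
    record_schedule=default_record_schedule,
    stop_when_copies_above: int | None = None,
    stop_when_fixed_cluster: bool = False,
    keep_final_population: bool = False,
    replicate: int = 0,
) -> Trajectory:
    """Run one invasion for ``params.generations`` generations or until the
    TE is lost, the population goes extinct (mean fitness < 0.1), an optional
    copy-number threshold is exceeded, or (optionally) a cluster insertion
    fixes. Deterministic given the generator state."""
    if rng is None:
        rng = rng_for_replicate(params.seed, replicate)
    model = fitness_model_of(params)
    pop = init_population(arch, params.N, params.n_seed, rng).refresh(arch, model)
    records = [summarize(pop, 0)]
    status = "completed"
    two_n = 2 * params.N
    for gen in range(1, params.generations + 1):
        if pop.total_copies == 0:
            status = "lost"
            break
        if float(pop.fitness.mean()) < 0.1:
            status = "extinct"
            break
        try:
            pop, novel = step_generation(pop, arch, params, rng)
        except ExtinctionError:
            status = "extinct"
            break
        recorded = False
        if record_schedule(gen) or gen == params.generations:
            records.append(summarize(pop, novel))
            recorded = True
        if stop_when_copies_above is not None and pop.total_copies > stop_when_copies_above:
            if not recorded:
                records.append(summarize(pop, novel))
            break
        if stop_when_fixed_cluster:
            fixed = (
                records[-1].fixed_cluster_sites > 0
                if recorded
                else _has_fixed_cluster(pop, two_n)
            )
            if fixed:
                if not recorded:
                    records.append(summarize(pop, novel))
                break
    else:
        gen = params.generations
    if status == "completed" and pop.total_copies == 0:
        status = "lost"
    if records[-1].generation != pop.generation:
        records.append(summarize(pop, 0 if status != "completed" else novel))
    return Trajectory(
        params=params,
        records=records,
        status=status,
        replicate=replicate,
        final_population=pop if keep_final_population else None,
    )


def _has_fixed_cluster(pop: Population, two_n: int) -> bool:
    sub = pop.sites[pop.site_class == SiteClass.CLUSTER]
    if sub.size < two_n:
        return False
    _, cnt = np.unique(sub, return_counts=True)
    return bool(np.any(cnt == two_n))


def rng_for_replicate(seed: int, replicate: int) -> np.random.Generator:
    """Independent, individually reproducible stream for replicate k."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def run_replicates(
    arch: GenomeArchitecture,
    params: SimulationParameters,
    *,
    established_only: bool = False,
    max_attempts: int | None = None,
    **run_kwargs,
) -> list[Trajectory]:
    """Run ``params.replicates`` independent invasions.

    With ``established_only=True``, replicates that lose the TE are discarded
    and further substreams are drawn until the requested number of
    established invasions is reached (mirroring the convention of ignoring
    failed invasions)."""
    if params.replicates < 1:
        raise ValueError("replicates must be >= 1")
    if max_attempts is None:
        max_attempts = 50 * params.replicates
    out: list[Trajectory] = []
    rep = 0
    while len(out) < params.replicates:
        if rep >= max_attempts:
            raise RuntimeError(
                f"could not collect {params.replicates} established invasions "
                f"in {max_attempts} attempts"
            )
        traj = run_invasion(
            arch, params, rng_for_replicate(params.seed, rep), replicate=rep, **run_kwargs
        )
        rep += 1
        if established_only and not traj.established:
            continue
        out.append(traj)
    return out
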
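"""Diploid populations as sparse sets of occupied insertion sites.

The population state is stored flat: one int64 array of global site indices,
segmented into 2N haplotypes by an index-pointer array (haplotypes ``2i`` and
``2i+1`` belong to individual ``i``). This keeps the per-generation engine
fully vectorized while still exposing per-individual views
(:class:`Individual`, :class:`Haplotype`) for inspection and testing.

Per-individual copy counts (total / cluster / reference) and fitness are
cached on the population and refreshed whenever a new generation is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import GenomeArchitecture, SiteClass
from .fitness import FitnessModel, fitness_array


@dataclass
class Haplotype:
    """Sorted set of occupied global site indices on one chromosome set."""

    sites: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.sites = np.sort(self.sites)
        if self.sites.size and np.any(np.diff(self.sites) == 0):
            raise ValueError("duplicate site within a haplotype")

    def __len__(self) -> int:
        return int(self.sites.size)


@dataclass
class Individual:
    """A diploid: two haplotypes plus cached copy counts and fitness."""

    hap1: Haplotype
    hap2: Haplotype
    n_total: int = 0
    n_cluster: int = 0
    n_reference: int = 0
    fitness: float = 1.0

    @classmethod
    def from_haplotypes(
        cls,
        hap1: Haplotype,
        hap2: Haplotype,
        arch: GenomeArchitecture,
        model: FitnessModel | None = None,
    ) -> "Individual":
        sites = np.concatenate([hap1.sites, hap2.sites])
        site_cls = arch.classify_sites(sites) if sites.size else np.empty(0, np.int8)
        n_clu = int(np.count_nonzero(site_cls == SiteClass.CLUSTER))
        n_ref = int(np.count_nonzero(site_cls == SiteClass.REFERENCE))
        ind = cls(hap1, hap2, int(sites.size), n_clu, n_ref)
        if model is not None:
            from .fitness import fitness as _fit

            ind.fitness = _fit(ind, arch, model)
        return ind

    @property
    def sites(self) -> np.ndarray:
        return np.concatenate([self.hap1.sites, self.hap2.sites])


class Population:
    """N diploid individuals at one generation.

    Attributes
    ----------
    sites : int64 array of all TE copies (one entry per copy).
    indptr : int64 array of length 2N+1; haplotype h owns
        ``sites[indptr[h]:indptr[h+1]]``.
    site_class, n_total, n_cluster, n_reference, fitness : caches refreshed
        via :meth:`refresh` against an architecture and fitness model.
    """

    __slots__ = (
        "sites",
        "indptr",
        "N",
        "generation",
        "site_class",
        "site_chrom",
        "n_total",
        "n_cluster",
        "n_reference",
        "fitness",
    )

    def __init__(
        self,
        sites: np.ndarray,
        indptr: np.ndarray,
        N: int,
        generation: int = 0,
    ):
        self.sites = np.asarray(sites, dtype=np.int64)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        if self.indptr.size != 2 * N + 1:
            raise ValueError("indptr must have length 2N+1")
        if self.indptr[-1] != self.sites.size:
            raise ValueError("indptr inconsistent with sites array")
        self.N = int(N)
        self.generation = int(generation)
        self.site_class = None
        self.site_chrom = None
        self.n_total = None
        self.n_cluster = None
        self.n_reference = None
        self.fitness = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_haplotype_lists(
        cls, haplotypes: list[np.ndarray], generation: int = 0
    ) -> "Population":
        if len(haplotypes) % 2:
            raise ValueError("need an even number of haplotypes")
        counts = np.array([len(h) for h in haplotypes], dtype=np.int64)
        indptr = np.concatenate(([0], np.cumsum(counts)))
        sites = (
            np.concatenate([np.asarray(h, dtype=np.int64) for h in haplotypes])
            if counts.sum()
            else np.empty(0, np.int64)
        )
        return cls(sites, indptr, N=len(haplotypes) // 2, generation=generation)

    def refresh(self, arch: GenomeArchitecture, model: FitnessModel) -> "Population":
        """Recompute per-copy classes, per-individual counts and fitness."""
        self.site_class = arch.classify_sites(self.sites)
        self.site_chrom = arch.chrom_of(self.sites)
        owner = self.copy_owner_individual()
        self.n_total = np.bincount(owner, minlength=self.N)
        self.n_cluster = np.bincount(
            owner[self.site_class == SiteClass.CLUSTER], minlength=self.N
        )
        self.n_reference = np.bincount(
            owner[self.site_class == SiteClass.REFERENCE], minlength=self.N
        )
        self.fitness = fitness_array(
            self.n_total, self.n_cluster, self.n_reference, model
        )
        return self

    # -- views --------------------------------------------------------------

    @property
    def total_copies(self) -> int:
        return int(self.sites.size)

    def copy_owner_hap(self) -> np.ndarray:
        """Haplotype index (0..2N-1) of each copy."""
        counts = np.diff(self.indptr)
        return np.repeat(np.arange(2 * self.N, dtype=np.int64), counts)

    def copy_owner_individual(self) -> np.ndarray:
        return self.copy_owner_hap() >> 1

    def haplotype(self, h: int) -> Haplotype:
        return Haplotype(self.sites[self.indptr[h] : self.indptr[h + 1]])

    def individual(
        self,
        i: int,
        arch: GenomeArchitecture | None = None,
        model: FitnessModel | None = None,
    ) -> Individual:
        h1, h2 = self.haplotype(2 * i), self.haplotype(2 * i + 1)
        if arch is None:
            return Individual(h1, h2, n_total=len(h1) + len(h2))
        return Individual.from_haplotypes(h1, h2, arch, model)

    def canonical_haplotypes(self) -> list[np.ndarray]:
        """Site-sorted per-haplotype arrays (for equality checks / IO)."""
        return [np.sort(self.sites[self.indptr[h] : self.indptr[h + 1]]) for h in range(2 * self.N)]


# -- spec operations --------------------------------------------------------


def init_population(
    arch: GenomeArchitecture,
    N: int,
    n_seed: int,
    rng: np.random.Generator,
) -> Population:
    """Seed ``n_seed`` insertions, each at a distinct uniformly drawn site,
    each on one uniformly drawn haplotype of one uniformly drawn individual
    (so every seeded site starts at frequency 1/2N)."""
    if n_seed > arch.total_bp:
        raise ValueError("cannot seed more distinct sites than the genome holds")
    chosen: set[int] = set()
    while len(chosen) < n_seed:
        draw = rng.integers(0, arch.total_bp, size=n_seed - len(chosen))
        chosen.update(int(s) for s in draw)
    sites = np.array(sorted(chosen), dtype=np.int64)
    owners = rng.integers(0, 2 * N, size=n_seed)
    order = np.argsort(owners, kind="stable")
    counts = np.bincount(owners, minlength=2 * N)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    return Population(sites[order], indptr, N=N, generation=0)


def allele_frequencies(pop: Population, arch: GenomeArchitecture) -> pd.DataFrame:
    """Per-site population allele frequencies.

    Returns a frame with columns ``site``, ``site_class``, ``count`` (number
    of haplotypes carrying the site) and ``freq`` = count / 2N. Every occupied
    site appears exactly once; a fixed site has freq 1.0.
    """
    uniq, counts = np.unique(pop.sites, return_counts=True)
    cls = arch.classify_sites(uniq) if uniq.size else np.empty(0, np.int8)
    return pd.DataFrame(
        {
            "site": uniq,
            "site_class": [SiteClass(int(c)).name for c in cls],
            "count": counts,
            "freq": counts / (2 * pop.N),
        }
    )


def has_cluster_insertion(ind: Individual, arch: GenomeArchitecture) -> bool:
    """True iff any site on either haplotype lies in a piRNA cluster
    (reference-region insertions never silence)."""
    sites = ind.sites
    if not sites.size:
        return False
    return bool(np.any(arch.classify_sites(sites) == SiteClass.CLUSTER))


def fraction_with_cluster(pop: Population, arch: GenomeArchitecture) -> float:
    """Proportion of individuals carrying at least one cluster insertion."""
    if pop.n_cluster is not None:
        return float(np.mean(pop.n_cluster > 0))
    cls = arch.classify_sites(pop.sites)
    owner = pop.copy_owner_individual()
    n_clu = np.bincount(owner[cls == SiteClass.CLUSTER], minlength=pop.N)
    return float(np.mean(n_clu > 0))


def zygosity_breakdown(
    pop: Population, arch: GenomeArchitecture
) -> tuple[float, float]:
    """Fractions of (heterozygous, homozygous) cluster-insertion genotypes.

    Each (individual, cluster site) pair with at least one copy counts once:
    heterozygous if the site sits on one haplotype, homozygous if on both.
    Aggregated over all cluster sites; returns (nan, nan) if no individual
    carries a cluster insertion.
    """
    cls = arch.classify_sites(pop.sites)
    mask = cls == SiteClass.CLUSTER
    if not np.any(mask):
        return (float("nan"), float("nan"))
    owner = pop.copy_owner_individual()[mask]
    key = owner * np.int64(arch.total_bp) + pop.sites[mask]
    _, per_genotype = np.unique(key, return_counts=True)
    het = int(np.count_nonzero(per_genotype == 1))
    hom = int(np.count_nonzero(per_genotype == 2))
    total = het + hom
    return het / total, hom / total


def sfs(
    pop: Population,
    arch: GenomeArchitecture,
    site_class: SiteClass | str,
    bins,
) -> np.ndarray:
    """Binned site-frequency spectrum for one site class.

    ``bins`` are edges partitioning (0, 1]; counts include segregating and
    fixed sites of the class.
    """
    if isinstance(site_class, str):
        site_class = SiteClass[site_class.upper()]
    freqs = allele_frequencies(pop, arch)
    f = freqs.loc[freqs["site_class"] == site_class.name, "freq"].to_numpy()
    bins = np.asarray(bins, dtype=float)
    # right-closed bins so that a frequency equal to an edge (incl. 1.0)
    # lands in the bin it closes
    idx = np.searchsorted(bins, f, side="left") - 1
    idx = np.clip(idx, 0, len(bins) - 2)
    return np.bincount(idx, minlength=len(bins) - 1)


# -- snapshot IO -------------------------------------------------------------


def write_snapshot(
    pop: Population,
    arch: GenomeArchitecture,
    path,
    replicate: int = 0,
) -> None:
    """Write a population snapshot as TSV: one row per TE copy with columns
    (replicate, generation, individual, haplotype, site, site_class)."""
    cls = arch.classify_sites(pop.sites)
    hap = pop.copy_owner_hap()
    df = pd.DataFrame(
        {
            "replicate": replicate,
            "generation": pop.generation,
            "individual": hap >> 1,
            "haplotype": hap & 1,
            "site": pop.sites,
            "site_class": [SiteClass(int(c)).name for c in cls],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# N\t{pop.N}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_snapshot(path) -> Population:
    """Restore a population from :func:`write_snapshot` output."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# N\t"):
            raise ValueError("snapshot missing '# N' header line")
        N = int(header.split("\t")[1])
        df = pd.read_csv(fh, sep="\t")
    generation = int(df["generation"].iloc[0]) if len(df) else 0
    hap_index = df["individual"].to_numpy() * 2 + df["haplotype"].to_numpy()
    order = np.argsort(hap_index, kind="stable")
    counts = np.bincount(hap_index, minlength=2 * N)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    sites = df["site"].to_numpy(dtype=np.int64)[order]
    return Population(sites, indptr, N=N, generation=generation)
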
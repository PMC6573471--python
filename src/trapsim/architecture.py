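"""Simulated genome architecture.

A genome is an ordered list of chromosomes, each carrying an optional piRNA
cluster at its start and an optional neutral reference region at its end.
Every base pair is a potential TE insertion site; sites are addressed by a
0-based, half-open global index obtained by concatenating chromosomes.

Site classes:

* ``CLUSTER`` -- a TE insertion here silences the whole family in trans
  (dominant, a single heterozygous copy suffices).
* ``REFERENCE`` -- neutral control region: insertions neither silence, nor
  transpose, nor affect fitness.
* ``GENOMIC`` -- everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

MB = 1_000_000
KB = 1_000


class SiteClass(IntEnum):
    GENOMIC = 0
    CLUSTER = 1
    REFERENCE = 2


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: length, uniform recombination rate, cluster/ref sizes.

    Parameters
    ----------
    length_bp:
        Chromosome length in base pairs (> 0).
    recomb_rate:
        Recombination rate in cM/Mb (>= 0). Crossover counts per meiosis are
        Poisson with mean ``recomb_rate * length_Mb / 100``.
    cluster_len_bp:
        piRNA-cluster length in bp; the cluster occupies the chromosome start.
    ref_len_bp:
        Neutral reference-region length in bp; occupies the chromosome end.
    """

    length_bp: int
    recomb_rate: float
    cluster_len_bp: int = 0
    ref_len_bp: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recombination rate must be non-negative")
        if self.cluster_len_bp < 0 or self.ref_len_bp < 0:
            raise ValueError("cluster/reference lengths must be non-negative")
        if self.cluster_len_bp + self.ref_len_bp > self.length_bp:
            raise ValueError(
                "cluster + reference regions exceed chromosome length"
            )


class GenomeArchitecture:
    """Immutable genome layout with precomputed interval tables."""

    def __init__(self, chromosomes: Sequence[ChromosomeSpec]):
        if not chromosomes:
            raise ValueError("need at least one chromosome")
        self.chromosomes: tuple[ChromosomeSpec, ...] = tuple(chromosomes)
        lengths = np.array([c.length_bp for c in self.chromosomes], dtype=np.int64)
        self.chrom_starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        self.chrom_ends = np.cumsum(lengths)
        self.total_bp = int(lengths.sum())
        self.total_cluster_bp = int(sum(c.cluster_len_bp for c in self.chromosomes))
        self.total_ref_bp = int(sum(c.ref_len_bp for c in self.chromosomes))
        # Poisson crossover mean per meiosis per chromosome (cM/Mb semantics).
        lam = np.array(
            [c.recomb_rate * (c.length_bp / MB) / 100.0 for c in self.chromosomes]
        )
        lam[lengths < 2] = 0.0  # a 1-bp chromosome cannot recombine
        self.crossover_lambda = lam
        # Interval table for site classification: bounds[i] .. bounds[i+1]
        # has class interval_class[i].
        bounds: list[int] = []
        classes: list[int] = []
        for start, end, c in zip(self.chrom_starts, self.chrom_ends, self.chromosomes):
            cuts = [
                (int(start), int(start) + c.cluster_len_bp, SiteClass.CLUSTER),
                (
                    int(start) + c.cluster_len_bp,
                    int(end) - c.ref_len_bp,
                    SiteClass.GENOMIC,
                ),
                (int(end) - c.ref_len_bp, int(end), SiteClass.REFERENCE),
            ]
            for lo, hi, cls in cuts:
                if hi > lo:
                    bounds.append(lo)
                    classes.append(int(cls))
        self._bounds = np.array(bounds, dtype=np.int64)
        self._classes = np.array(classes, dtype=np.int8)

    # -- derived quantities -------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def cluster_fraction(self) -> float:
        return self.total_cluster_bp / self.total_bp

    @property
    def ref_fraction(self) -> float:
        return self.total_ref_bp / self.total_bp

    # -- site queries -------------------------------------------------------

    def classify_sites(self, sites: np.ndarray) -> np.ndarray:
        """Vectorized site classification; returns int8 SiteClass codes."""
        sites = np.asarray(sites)
        if sites.size and (sites.min() < 0 or sites.max() >= self.total_bp):
            raise ValueError("site index out of range")
        idx = np.searchsorted(self._bounds, sites, side="right") - 1
        return self._classes[idx]

    def chrom_of(self, sites: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.chrom_ends, np.asarray(sites), side="right")

    def class_site_counts(self) -> dict[SiteClass, int]:
        genomic = self.total_bp - self.total_cluster_bp - self.total_ref_bp
        return {
            SiteClass.GENOMIC: genomic,
            SiteClass.CLUSTER: self.total_cluster_bp,
            SiteClass.REFERENCE: self.total_ref_bp,
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeArchitecture({self.n_chromosomes} chromosomes, "
            f"{self.total_bp / MB:g} Mb, clusters {self.cluster_fraction:.2%})"
        )


def build_architecture(
    chrom_mb: Sequence[float],
    rr_cm_mb: Sequence[float],
    cluster_kb: Sequence[float],
    ref_kb: Sequence[float] | None = None,
) -> GenomeArchitecture:
    """Build a genome from per-chromosome sizes (Mb), recombination rates
    (cM/Mb), cluster sizes (kb) and optional reference-region sizes (kb).

    ``ref_kb`` may be empty/None, meaning no reference regions.
    """
    if ref_kb is None or len(ref_kb) == 0:
        ref_kb = [0.0] * len(chrom_mb)
    if not (len(chrom_mb) == len(rr_cm_mb) == len(cluster_kb) == len(ref_kb)):
        raise ValueError("per-chromosome lists must have equal length")
    chroms = [
        ChromosomeSpec(
            length_bp=int(round(mb * MB)),
            recomb_rate=float(rr),
            cluster_len_bp=int(round(ck * KB)),
            ref_len_bp=int(round(rk * KB)),
        )
        for mb, rr, ck, rk in zip(chrom_mb, rr_cm_mb, cluster_kb, ref_kb)
    ]
    return GenomeArchitecture(chroms)


def classify_site(arch: GenomeArchitecture, site: int) -> SiteClass:
    """Class of a single global site index."""
    if not 0 <= site < arch.total_bp:
        raise ValueError(f"site {site} out of range [0, {arch.total_bp})")
    return SiteClass(int(arch.classify_sites(np.array([site]))[0]))


def sample_insertion_site(arch: GenomeArchitecture, rng: np.random.Generator) -> int:
    """Uniformly sample one insertion site over the whole genome."""
    return int(rng.integers(0, arch.total_bp))


def sample_insertion_sites(
    arch: GenomeArchitecture, n: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.integers(0, arch.total_bp, size=n, dtype=np.int64)


def default_architecture() -> GenomeArchitecture:
    """Five 10-Mb chromosomes, rr 4 cM/Mb, one 300-kb cluster per chromosome
    (clusters total 3% of the genome)."""
    return build_architecture([10] * 5, [4] * 5, [300] * 5)


SCENARIO_NAMES = (
    "default",
    "flamenco",
    "flamenco_recombining",
    "germline",
    "germline_recombining",
    "dmel_germline",
    "dmel_somatic",
)


def predefined_scenarios(name: str):
    """Return ``(GenomeArchitecture, SimulationParameters)`` for a named
    study scenario.

    * ``default`` -- five 10-Mb chromosomes, 3% clusters, rr 4.
    * ``flamenco`` / ``flamenco_recombining`` -- five 2-Mb chromosomes, a
      single 1-Mb cluster (10% of genome) on the first chromosome, with
      crossovers off (somatic-pathway analogue) or at 4 cM/Mb.
    * ``germline`` / ``germline_recombining`` -- same genome, five 200-kb
      clusters distributed over the chromosomes (same total trap size).
    * ``dmel_germline`` -- 200-Mb genome, clusters on five chromosomes
      totalling 3.5% of the genome.
    * ``dmel_somatic`` -- 200-Mb genome, one non-recombining 300-kb cluster
      (0.15% of the genome).
    """
    from .params import SimulationParameters

    p = SimulationParameters()
    if name == "default":
        return default_architecture(), p
    if name == "flamenco":
        return build_architecture([2] * 5, [0] * 5, [1000, 0, 0, 0, 0]), p
    if name == "flamenco_recombining":
        return build_architecture([2] * 5, [4] * 5, [1000, 0, 0, 0, 0]), p
    if name == "germline":
        return build_architecture([2] * 5, [0] * 5, [200] * 5), p
    if name == "germline_recombining":
        return build_architecture([2] * 5, [4] * 5, [200] * 5), p
    if name == "dmel_germline":
        return build_architecture([40] * 5, [4] * 5, [1400] * 5), p
    if name == "dmel_somatic":
        return build_architecture([40] * 5, [0, 4, 4, 4, 4], [300, 0, 0, 0, 0]), p
    raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
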
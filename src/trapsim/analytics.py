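"""Closed-form results, phase annotation and outcome classification.

Invasion phases
---------------
* rapid invasion -- near-unconstrained copy-number growth;
* shotgun -- containment by many segregating cluster insertions; onset is
  the first generation at which >= 99% of individuals carry at least one
  cluster insertion;
* inactive -- permanent silencing after the first cluster insertion fixes.

Outcome classes (evaluated at a chosen generation): ``lost``, ``extinct``,
``three_phase`` (a cluster insertion fixed) and ``tsc_balance`` --
transposition-selection-cluster balance, the equilibrium in which copy
numbers plateau while cluster insertions keep segregating and the TE stays
active in part of the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import GenomeArchitecture
from .engine import Trajectory, run_invasion, rng_for_replicate
from .params import SimulationParameters
from .population import Population, allele_frequencies

__all__ = [
    "establishment_probability",
    "fraction_active",
    "PhaseStats",
    "PhaseAnnotation",
    "annotate_phases",
    "OutcomeClass",
    "classify_outcome",
    "quadrant_label",
    "parameter_space_scan",
    "selection_contrast",
    "abundance_quantiles",
]


def establishment_probability(u: float, n: int) -> float:
    """Probability that an invasion seeded with ``n`` insertions at frequency
    1/2N escapes stochastic loss.

    A single neutral low-frequency insertion that transposes at rate ``u`` is
    lost with probability roughly ``pl = 1 - 2u`` (floored at 0), so the
    invasion establishes with probability ``pe = 1 - pl**n``.
    """
    if u < 0:
        raise ValueError("u must be non-negative")
    if n < 0:
        raise ValueError("n must be non-negative")
    pl = max(0.0, 1.0 - 2.0 * u)
    return 1.0 - pl**n


def fraction_active(freqs) -> float:
    """Expected fraction of individuals without any cluster insertion,
    ``fa = prod_i (1 - p_i)**2``, under random union of gametes."""
    p = np.asarray(freqs, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return float(np.prod((1.0 - p) ** 2))


# ---------------------------------------------------------------------------
# phase annotation
# ---------------------------------------------------------------------------


@dataclass
class PhaseStats:
    name: str
    start: int
    end: int | None  # inclusive; None = open-ended
    length: int | None
    abundance_start: float
    cluster_start: float
    stability_sd: float


@dataclass
class PhaseAnnotation:
    """Contiguous, ordered phases of one replicate (later phases may be
    absent if the replicate never reached them)."""

    phases: list[PhaseStats]
    shotgun_onset: int | None
    inactive_onset: int | None

    def phase(self, name: str) -> PhaseStats | None:
        for p in self.phases:
            if p.name == name:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.phases])


def annotate_phases(traj: Trajectory) -> PhaseAnnotation:
    """Split a trajectory into rapid-invasion / shotgun / inactive phases.

    Boundaries are detected on the recorded generations: the shotgun phase
    starts at the first record with ``fraction_with_cluster >= 0.99`` and the
    inactive phase at the first record with a fixed cluster site.
    """
    if not traj.records:
        raise ValueError("empty trajectory")
    df = traj.to_frame()
    gens = df["generation"].to_numpy()
    shot = df.index[df["fraction_with_cluster"] >= 0.99]
    fixed = df.index[df["fixed_cluster_sites"] >= 1]
    shotgun_onset = int(gens[shot[0]]) if len(shot) else None
    inactive_onset = int(gens[fixed[0]]) if len(fixed) else None
    if inactive_onset is not None and (
        shotgun_onset is None or shotgun_onset > inactive_onset
    ):
        # a fixed cluster site implies every individual carries it
        shotgun_onset = inactive_onset

    last_gen = int(gens[-1])
    bounds: list[tuple[str, int, int | None]] = []
    if shotgun_onset is None:
        bounds.append(("rapid_invasion", 0, None))
    else:
        if shotgun_onset > 0:
            bounds.append(("rapid_invasion", 0, shotgun_onset - 1))
        else:
            bounds.append(("rapid_invasion", 0, -1))  # zero-length
        if inactive_onset is None:
            bounds.append(("shotgun", shotgun_onset, None))
        else:
            if inactive_onset > shotgun_onset:
                bounds.append(("shotgun", shotgun_onset, inactive_onset - 1))
            bounds.append(("inactive", inactive_onset, None))

    phases = []
    for name, start, end in bounds:
        hi = last_gen if end is None else end
        sel = (gens >= start) & (gens <= hi)
        sub = df.loc[sel]
        if len(sub):
            abundance = float(sub["mean_copies"].iloc[0])
            cluster = float(sub["mean_cluster"].iloc[0])
            sd = float(sub["mean_copies"].std(ddof=1)) if len(sub) > 1 else 0.0
        else:  # zero-length rapid invasion
            abundance = float(df["mean_copies"].iloc[0])
            cluster = float(df["mean_cluster"].iloc[0])
            sd = 0.0
        length = None if end is None else max(0, end - start + 1)
        phases.append(
            PhaseStats(
                name=name,
                start=start,
                end=end,
                length=length,
                abundance_start=abundance,
                cluster_start=cluster,
                stability_sd=sd,
            )
        )
    return PhaseAnnotation(
        phases=phases, shotgun_onset=shotgun_onset, inactive_onset=inactive_onset
    )


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeClass:
    outcome: str  # lost | extinct | three_phase | tsc_balance | other
    quadrant: int  # from (N*u vs 1, N*x vs 1)


def quadrant_label(N: int, u: float, x: float) -> int:
    """1: Nu>1 & Nx>1; 2: Nu>1 only; 3: neither; 4: Nx>1 only."""
    nu, nx = N * u, N * x
    if nu > 1 and nx > 1:
        return 1
    if nu > 1:
        return 2
    if nx > 1:
        return 4
    return 3


def classify_outcome(
    traj: Trajectory,
    eval_generation: int | None = None,
    window: float = 0.2,
    slope_tol: float = 1e-3,
    activity_tol: float = 0.01,
) -> OutcomeClass:
    """Classify a replicate at ``eval_generation`` (default: last record).

    ``lost`` if the TE died out; ``extinct`` if mean fitness fell below 0.1;
    ``three_phase`` if a cluster insertion fixed; ``tsc_balance`` if the TE
    persists with segregating (unfixed) cluster insertions in fewer than 99%
    of individuals, a stable copy number (|OLS slope| of the trailing
    ``window`` fraction of records below ``slope_tol`` copies/generation) and
    persistent transposition activity (mean novel insertions per individual
    in the window >= ``activity_tol``); ``other`` otherwise.
    """
    q = quadrant_label(traj.params.N, traj.params.u, traj.params.x)
    if traj.status == "extinct":
        return OutcomeClass("extinct", q)
    df = traj.to_frame()
    if eval_generation is not None:
        df = df[df["generation"] <= eval_generation]
    if not len(df):
        raise ValueError("trajectory has no records before eval_generation")
    last = df.iloc[-1]
    if traj.status == "lost" or last["mean_copies"] == 0:
        return OutcomeClass("lost", q)
    if last["mean_fitness"] < 0.1:
        return OutcomeClass("extinct", q)
    if (df["fixed_cluster_sites"] >= 1).any():
        return OutcomeClass("three_phase", q)
    gmax = df["generation"].iloc[-1]
    tail = df[df["generation"] >= (1 - window) * gmax]
    stable = False
    if len(tail) >= 3:
        slope = np.polyfit(
            tail["generation"].to_numpy(float), tail["mean_copies"].to_numpy(float), 1
        )[0]
        stable = abs(slope) < slope_tol
    active = float(tail["novel_per_individual"].mean()) >= activity_tol
    if (
        stable
        and active
        and last["fraction_with_cluster"] < 0.99
        and last["seg_sites_cluster"] > 0
    ):
        return OutcomeClass("tsc_balance", q)
    return OutcomeClass("other", q)


def parameter_space_scan(
    arch: GenomeArchitecture,
    u_range: tuple[float, float],
    x_range: tuple[float, float],
    n_points: int,
    generations: int,
    seed: int,
    *,
    N: int = 1000,
    model: str = "linear",
    n_seed: int = 1000,
    t: float = 1.0,
    slope_tol: float = 1e-3,
    activity_tol: float = 0.01,
) -> pd.DataFrame:
    """Random scan of the (u, x) parameter plane.

    Each point draws u and x log-uniformly, runs one invasion seeded with
    ``n_seed`` insertions at frequency 1/2N, and records the outcome at the
    final generation. Returns columns (u, x, N, Nu, Nx, outcome, quadrant).
    """
    if min(u_range) <= 0 or min(x_range) <= 0:
        raise ValueError("scan ranges must be positive (log-uniform draws)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(987,)))
    us = np.exp(rng.uniform(np.log(u_range[0]), np.log(u_range[1]), n_points))
    xs = np.exp(rng.uniform(np.log(x_range[0]), np.log(x_range[1]), n_points))
    rows = []
    for i, (u, x) in enumerate(zip(us, xs)):
        params = SimulationParameters(
            u=float(u),
            x=float(x),
            t=t,
            model=model,
            N=N,
            n_seed=n_seed,
            generations=generations,
            replicates=1,
            seed=seed,
        )
        traj = run_invasion(
            arch,
            params,
            rng_for_replicate(seed, i),
            stop_when_fixed_cluster=True,
            replicate=i,
        )
        oc = classify_outcome(traj, slope_tol=slope_tol, activity_tol=activity_tol)
        rows.append(
            {
                "u": float(u),
                "x": float(x),
                "N": N,
                "Nu": N * float(u),
                "Nx": N * float(x),
                "outcome": oc.outcome,
                "quadrant": oc.quadrant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection contrast and abundance expectations
# ---------------------------------------------------------------------------


def selection_contrast(pops: list[Population], arch: GenomeArchitecture) -> dict:
    """Compare allele frequencies of cluster vs reference vs genomic
    insertions across replicate populations.

    For each population, the mean allele frequency per site class is taken;
    classes are then compared across replicates with two-sided two-sample
    rank-sum tests. Reference regions must be configured.
    """
    if arch.total_ref_bp == 0:
        raise ValueError("architecture has no reference regions configured")
    per_class: dict[str, list[float]] = {"CLUSTER": [], "REFERENCE": [], "GENOMIC": []}
    for pop in pops:
        freqs = allele_frequencies(pop, arch)
        for name in per_class:
            sub = freqs.loc[freqs["site_class"] == name, "freq"]
            per_class[name].append(float(sub.mean()) if len(sub) else np.nan)
    means = {k: float(np.nanmean(v)) for k, v in per_class.items()}

    def _test(a: str, b: str) -> float:
        xa = np.asarray(per_class[a], float)
        xb = np.asarray(per_class[b], float)
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        return float(stats.ranksums(xa, xb).pvalue)

    return {
        "mean_freq": means,
        "per_replicate": {k: np.asarray(v) for k, v in per_class.items()},
        "p_cluster_vs_reference": _test("CLUSTER", "REFERENCE"),
        "p_cluster_vs_genomic": _test("CLUSTER", "GENOMIC"),
        "p_reference_vs_genomic": _test("REFERENCE", "GENOMIC"),
    }


def plateau_abundance(traj: Trajectory, haploid: bool = True) -> float:
    """Copy-number plateau of one replicate: the last recorded generation of
    its shotgun/inactive phase (the final record if neither was reached),
    as haploid (= diploid mean / 2) or diploid abundance."""
    rec = traj.records[-1]
    value = rec.mean_copies
    return value / 2 if haploid else value


def abundance_quantiles(
    trajs: list[Trajectory],
    q_low: float = 0.05,
    q_high: float = 0.95,
    haploid: bool = True,
) -> tuple[float, float]:
    """Quantile interval of plateau abundance across replicates."""
    if len(trajs) < 20:
        raise ValueError("need at least 20 replicates for quantile estimates")
    vals = np.array([plateau_abundance(t, haploid=haploid) for t in trajs])
    return (
        float(np.quantile(vals, q_low)),
        float(np.quantile(vals, q_high)),
    )
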
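"""Simulation parameter container shared by the engine and scenario tables."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class SimulationParameters:
    """All tunable knobs of one invasion simulation.

    Attributes
    ----------
    u:
        Transposition rate per TE copy per generation.
    v:
        Excision rate per copy per generation.
    x:
        Negative fitness effect per TE copy.
    t:
        Exponent of the exponential fitness model ``w = 1 - x * n**t``;
        ``t = 1`` recovers the linear model.
    model:
        ``"linear"``, ``"exponential"`` or ``"cluster_neutral"`` (cluster
        insertions excluded from the selected copy count).
    N:
        Diploid population size (constant across generations).
    n_seed:
        TE insertions randomly distributed in the starting population, each
        at frequency 1/2N.
    generations:
        Generations to simulate (unless the invasion is lost or the
        population goes extinct first).
    replicates:
        Independent replicate invasions.
    seed:
        Master seed; replicate k runs on an independent substream derived
        from ``(seed, k)``.
    """

    u: float = 0.1
    v: float = 0.0
    x: float = 0.0
    t: float = 1.0
    model: str = "linear"
    N: int = 1000
    n_seed: int = 10
    generations: int = 5000
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u < 0 or self.v < 0 or self.x < 0:
            raise ValueError("rates u, v and effect x must be non-negative")
        if self.t < 1:
            raise ValueError("exponent t must be >= 1")
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if self.n_seed < 0:
            raise ValueError("n_seed must be >= 0")
        if self.model not in ("linear", "exponential", "cluster_neutral"):
            raise ValueError(f"unknown fitness model {self.model!r}")

    @property
    def u_net(self) -> float:
        """Net transposition rate u' = u - v."""
        return self.u - self.v

    def evolve(self, **changes) -> "SimulationParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
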
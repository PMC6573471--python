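"""Host fitness under the three selection models.

``w = max(0, 1 - x * n**t)`` where ``n`` is the selected TE copy count of a
diploid individual:

* linear (``t = 1``) and exponential models count all copies except those in
  neutral reference regions -- cluster insertions are deleterious too;
* the cluster-neutral model additionally excludes cluster copies, so an
  individual carrying only cluster insertions has fitness 1.

Fitness is floored at 0; individuals with w = 0 never reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODEL_KINDS = ("linear", "exponential", "cluster_neutral")


@dataclass(frozen=True)
class FitnessModel:
    kind: str = "linear"
    x: float = 0.0
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown fitness model {self.kind!r}")
        if self.x < 0:
            raise ValueError("x must be non-negative")
        if self.t < 1:
            raise ValueError("t must be >= 1")


def selected_copy_number(
    n_total: np.ndarray, n_cluster: np.ndarray, n_reference: np.ndarray, model: FitnessModel
) -> np.ndarray:
    """Copy count entering the fitness function (reference copies never count;
    cluster copies are exempt only under the cluster-neutral model)."""
    n = np.asarray(n_total) - np.asarray(n_reference)
    if model.kind == "cluster_neutral":
        n = n - np.asarray(n_cluster)
    return n


def fitness_array(
    n_total: np.ndarray,
    n_cluster: np.ndarray,
    n_reference: np.ndarray,
    model: FitnessModel,
) -> np.ndarray:
    """Vectorized fitness for per-individual copy counts."""
    n = selected_copy_number(n_total, n_cluster, n_reference, model).astype(float)
    if model.x == 0.0:
        return np.ones_like(n)
    if model.kind == "exponential" and model.t != 1.0:
        w = 1.0 - model.x * n**model.t
    else:
        w = 1.0 - model.x * n
    return np.maximum(w, 0.0)


def fitness(ind, arch, model: FitnessModel) -> float:
    """Fitness of a single individual (see :class:`trapsim.population.Individual`)."""
    w = fitness_array(
        np.array([ind.n_total]),
        np.array([ind.n_cluster]),
        np.array([ind.n_reference]),
        model,
    )
    return float(w[0])
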
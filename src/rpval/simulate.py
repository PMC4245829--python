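"""Seeded synthetic fixtures: null rank matrices and spiked expression data.

Everything here is a pure function of its configuration and seed, so tests
and examples need no external downloads.  The expression generator uses
independent Gaussian noise per experiment with a constant shift for the
spiked molecules — the simplest exchangeable model; the rank product method
itself is distribution-free, so the specific noise law is a documentation
choice, not a modelling commitment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .exact import ProblemSpec
from .pipeline import RankMatrix

__all__ = [
    "SpikeConfig",
    "simulate_null_ranks",
    "simulate_uniform_rhos",
    "simulate_expression",
]


@dataclass(frozen=True)
class SpikeConfig:
    """Design of a spiked fold-change matrix.

    ``n_de`` molecules are shifted by ``effect`` (mean log fold change) in
    every experiment on top of Normal(0, noise_sd) noise.
    """

    n: int
    k: int
    n_de: int
    effect: float
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_de <= self.n:
            raise ValueError("n_de must lie in [0, n]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_null_ranks(spec: ProblemSpec, seed: int) -> RankMatrix:
    """Rank matrix with independent uniform permutation columns."""
    rng = np.random.default_rng(seed)
    ranks = np.column_stack(
        [rng.permutation(spec.n) + 1 for _ in range(spec.k)]
    ).astype(np.int64)
    ids = tuple(f"mol{i}" for i in range(spec.n))
    return RankMatrix(ids=ids, ranks=ranks, direction="up")


def simulate_uniform_rhos(spec: ProblemSpec, count: int, seed: int) -> list[int]:
    """iid uniform integers on [1, n**k] (exact even when n**k exceeds int64)."""
    rng = random.Random(seed)
    top = spec.n_pow_k
    return [rng.randint(1, top) for _ in range(count)]


def simulate_expression(cfg: SpikeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spiked fold-change matrix and boolean truth labels.

    Null molecules draw Normal(0, noise_sd) per experiment; a random subset
    of ``n_de`` molecules is shifted by ``+effect`` in every experiment.
    """
    rng = np.random.default_rng(cfg.seed)
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.k))
    labels = np.zeros(cfg.n, dtype=bool)
    spiked = rng.choice(cfg.n, size=cfg.n_de, replace=False)
    labels[spiked] = True
    values[spiked, :] += cfg.effect
    return values, labels
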
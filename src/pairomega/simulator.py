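"""Simulation of pairwise codon alignments under the codon model.

Sites are independent and identically distributed.  For a reversible
model, drawing codon i at a site from the equilibrium frequencies and
codon j from row i of P(t) is equivalent to evolving the two sequences
from a common ancestor along a path of total length t, so a single
transition-matrix draw per site reproduces the pairwise sampling
distribution exactly.  No indels are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .alignment_io import PairAlignment
from .codon_model import (
    STANDARD_CODE,
    CodonFrequencies,
    build_rate_matrix,
    transition_probabilities,
)


@dataclass
class SimConfig:
    """One simulation condition."""

    L_c: int = 500
    t: float = 0.5
    omega: float = 0.5
    kappa: float = 2.0
    freqs: CodonFrequencies = field(default_factory=CodonFrequencies.equal)
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L_c < 1 or self.t < 0 or self.replicates < 1:
            raise ValueError("invalid simulation configuration")


def simulate_pair(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PairAlignment:
    """Draw one pairwise alignment of L_c codon sites."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = build_rate_matrix(config.freqs, kappa=config.kappa, omega=config.omega)
    P = transition_probabilities(model, config.t)
    pi = model.pi
    i = rng.choice(pi.size, size=config.L_c, p=pi)
    j = np.empty_like(i)
    # Draw j | i per unique ancestor codon so each row's distribution is
    # sampled with one vectorized call.
    for ci in np.unique(i):
        mask = i == ci
        row = P[ci] / P[ci].sum()
        j[mask] = rng.choice(pi.size, size=int(mask.sum()), p=row)
    codons = STANDARD_CODE.sense_codons
    return PairAlignment(
        names=("seq1", "seq2"),
        codons1=[codons[k] for k in i],
        codons2=[codons[k] for k in j],
    )


def replicate_rng(seed: int, cell_index: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator, reproducible in isolation."""
    return np.random.default_rng([seed, cell_index, replicate])


def simulate_study(
    grid: list[tuple[float, float]],
    L_c: int = 500,
    replicates: int = 100,
    seed: int = 0,
    kappa: float = 2.0,
    freqs: CodonFrequencies | None = None,
) -> Iterator[tuple[int, tuple[float, float], int, PairAlignment]]:
    """Yield (cell_index, (t, omega), replicate_index, alignment) tuples.

    Each replicate uses its own counter-derived RNG stream, so any single
    replicate can be regenerated without simulating the ones before it.
    """
    if freqs is None:
        freqs = CodonFrequencies.equal()
    for cell_index, (t, omega) in enumerate(grid):
        config = SimConfig(
            L_c=L_c, t=t, omega=omega, kappa=kappa, freqs=freqs, replicates=1
        )
        for rep in range(replicates):
            rng = replicate_rng(seed, cell_index, rep)
            yield cell_index, (t, omega), rep, simulate_pair(config, rng)
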
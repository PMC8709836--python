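"""Synthetic populations and synthetic banding-sequence maps.

Every downstream stage of the package is testable without field data:
this module draws multi-allelic arm genotype samples under
Hardy-Weinberg proportions with an optional fixation-index deviation F,

    P(ii) = p_i^2 + F p_i (1 - p_i),      P(ij) = 2 p_i p_j (1 - F),

(negative F gives heterozygote excess, the deviation the field data
shows), and plants known paracentric reversals into banding-sequence
maps so that the rearrangement solver can be scored against a known
answer.  Arms are simulated independently; the data model carries no
inter-arm linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np

from .bandmap import ARMS, BandRun, SequenceMap
from .popstats import ArmGenotype, GenotypeCounts, LarvaKaryotype, PopulationSample

__all__ = [
    "SimulationConfig",
    "genotype_distribution",
    "simulate_genotype_counts",
    "simulate_population",
    "simulate_derived_map",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling design for one synthetic population.

    ``freqs`` maps each arm to its banding-sequence frequency vector;
    ``f`` is the fixation-index deviation from Hardy-Weinberg in (-1, 1)
    (bounded below by feasibility of all genotype probabilities);
    ``b_prob`` is the per-larva B-chromosome carriage probability.
    """

    freqs: Mapping[str, Mapping[str, float]]
    n: int
    f: float = 0.0
    b_prob: float = 0.0
    seed: int = 0
    code: str = "SYN"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need n >= 1 larvae")
        if not -1.0 < self.f < 1.0:
            raise ValueError("fixation index must lie in (-1, 1)")
        if not 0.0 <= self.b_prob <= 1.0:
            raise ValueError("b_prob must lie in [0, 1]")
        for arm, vec in self.freqs.items():
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError(f"arm {arm}: frequencies must sum to 1")
            for p in vec.values():
                if p < 0:
                    raise ValueError(f"arm {arm}: negative frequency")
                if 0 < p < 1 and p * p + self.f * p * (1 - p) < 0:
                    raise ValueError(
                        f"arm {arm}: F={self.f} makes a homozygote "
                        "probability negative"
                    )


def genotype_distribution(
    vec: Mapping[str, float], f: float = 0.0
) -> dict[tuple[str, str], float]:
    """Genotype probabilities for one arm under the F-model."""
    ids = sorted(vec)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations_with_replacement(ids, 2):
        p, q = vec[a], vec[b]
        out[(a, b)] = p * p + f * p * (1 - p) if a == b else 2 * p * q * (1 - f)
    return out


def simulate_genotype_counts(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, GenotypeCounts]:
    """Fast path: multinomial genotype counts per arm (no larva detail)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    out: dict[str, GenotypeCounts] = {}
    for arm, vec in cfg.freqs.items():
        dist = genotype_distribution(vec, cfg.f)
        keys = list(dist)
        draws = rng.multinomial(cfg.n, np.asarray([dist[k] for k in keys]))
        out[arm] = {k: int(c) for k, c in zip(keys, draws) if c > 0}
    return out


def simulate_population(cfg: SimulationConfig) -> PopulationSample:
    """Draw a larva-level sample; reproducible given the seed."""
    rng = np.random.default_rng(cfg.seed)
    per_arm: dict[str, list[ArmGenotype]] = {}
    for arm in ARMS:
        vec = cfg.freqs.get(arm)
        if vec is None:
            raise ValueError(f"config missing arm {arm}")
        dist = genotype_distribution(vec, cfg.f)
        keys = list(dist)
        probs = np.asarray([dist[k] for k in keys])
        idx = rng.choice(len(keys), size=cfg.n, p=probs)
        per_arm[arm] = [ArmGenotype(*keys[i]) for i in idx]
    b_counts = (rng.random(cfg.n) < cfg.b_prob).astype(int)
    larvae = [
        LarvaKaryotype(
            {arm: per_arm[arm][i] for arm in ARMS}, b_chromosomes=int(b_counts[i])
        )
        for i in range(cfg.n)
    ]
    return PopulationSample(code=cfg.code, larvae=larvae)


def simulate_derived_map(
    reference: SequenceMap,
    k: int,
    seed: int | np.random.Generator = 0,
    serial: int = 99,
) -> tuple[SequenceMap, list[tuple[int, int]]]:
    """Plant ``k`` random paracentric reversals into a map.

    Reversals act at run granularity: a contiguous block of runs is
    reversed in place and each run's direction is flipped, so the result
    re-emits as valid notation.  The centromere is terminal and never
    inside a reversal.  Returns the derived map and the planted scenario
    as (start, end) run-index intervals (1-based, in order of
    application).
    """
    if k < 1:
        raise ValueError("need at least one planted reversal")
    if not reference.mapped:
        raise ValueError(f"{reference.name} is not band-mapped")
    runs = list(reference.runs)
    if len(runs) < 2 and runs[0].direction == 0:
        raise ValueError("degenerate reference: a single one-band run")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scenario: list[tuple[int, int]] = []
    for _ in range(k):
        while True:
            i, j = sorted(int(v) for v in rng.integers(0, len(runs), size=2))
            if i == j and runs[i].direction == 0:
                continue  # flipping a single band is a notational no-op
            break
        runs[i : j + 1] = [r.reversed_() for r in reversed(runs[i : j + 1])]
        scenario.append((i + 1, j + 1))
    derived = SequenceMap(
        reference.prefix, reference.species, reference.arm, serial, tuple(runs)
    )
    return derived, scenario
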
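"""Population data model, polymorphism indices and Hardy-Weinberg tests.

Alternative banding sequences of one chromosome arm segregate like
codominant alleles of a single locus: a larva's arm genotype is an
unordered pair of sequence ids, visible directly in the polytene
squash (a heterozygous arm forms an inversion loop).  This module turns
per-larva karyotypes (or aggregated genotype counts) into allele
frequencies, summary indices of chromosomal polymorphism, and
goodness-of-fit tests against Hardy-Weinberg proportions.

Conventions
-----------
* Each heterozygous arm genotype counts as ONE heterozygous inversion in
  the per-larva index, whether the two sequences differ by one reversal
  or several.
* Supernumerary B chromosomes are summarised as a carrier frequency but
  never enter the heterozygosity indices or the Hardy-Weinberg tests;
  they are a separate, genomic form of polymorphism.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .bandmap import ARMS, parse_sequence_id

__all__ = [
    "ArmGenotype",
    "LarvaKaryotype",
    "PopulationSample",
    "AlleleFrequencyTable",
    "PolymorphismSummary",
    "HWTestResult",
    "PoolCensus",
    "allele_frequencies",
    "polymorphism_summary",
    "quantitative_panel_means",
    "hw_expected",
    "hw_chi_square",
    "hw_exact_test",
    "pool_census",
    "sequence_key",
]

HET_EXCESS = "het excess"
HET_DEFICIT = "het deficit"
NO_DEVIATION = "none"


def sequence_key(seq_id: str) -> tuple[str, str, int]:
    """Identity key of a banding sequence: (species, arm, serial).

    The geographic prefix (p'/h') classifies a sequence's distribution,
    not its identity, so it is excluded from the key.
    """
    _prefix, species, arm, serial = parse_sequence_id(seq_id)
    return species, arm, serial


def _serial(seq_id: str) -> int:
    return parse_sequence_id(seq_id)[3]


def _arm_of(seq_id: str) -> str:
    return parse_sequence_id(seq_id)[2]


@dataclass(frozen=True)
class ArmGenotype:
    """Unordered pair of banding-sequence ids of one arm."""

    a: str
    b: str

    def __post_init__(self) -> None:
        arm_a, arm_b = _arm_of(self.a), _arm_of(self.b)
        if arm_a != arm_b:
            raise ValueError(f"genotype mixes arms: {self.a} / {self.b}")
        if _serial(self.a) > _serial(self.b):
            first, second = self.b, self.a
            object.__setattr__(self, "a", first)
            object.__setattr__(self, "b", second)

    @property
    def arm(self) -> str:
        return _arm_of(self.a)

    @property
    def heterozygous(self) -> bool:
        return sequence_key(self.a) != sequence_key(self.b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)

    def __str__(self) -> str:
        # field-style display, e.g. p'agiB1.2 for a B1/B2 heterozygote
        pa, sa, _, _ = parse_sequence_id(self.a)
        pb, sb, _, _ = parse_sequence_id(self.b)
        if (pa, sa) == (pb, sb):
            return f"{self.a}.{_serial(self.b)}"
        return f"{self.a}.{self.b}"


@dataclass(frozen=True)
class LarvaKaryotype:
    """Per-arm genotypes of one larva plus its B-chromosome count."""

    genotypes: Mapping[str, ArmGenotype]
    b_chromosomes: int = 0

    def __post_init__(self) -> None:
        missing = [arm for arm in ARMS if arm not in self.genotypes]
        if missing:
            raise ValueError(f"larva missing arms: {missing}")
        if self.b_chromosomes < 0:
            raise ValueError("negative B-chromosome count")

    @property
    def heterozygous_arms(self) -> list[str]:
        return [arm for arm in ARMS if self.genotypes[arm].heterozygous]


GenotypeCounts = dict[tuple[str, str], int]


@dataclass
class PopulationSample:
    """One collection site's sample: larvae or per-arm genotype counts."""

    code: str
    larvae: list[LarvaKaryotype] | None = None
    counts: dict[str, GenotypeCounts] | None = None
    b_carriers: int | None = None
    site: dict | None = None

    def __post_init__(self) -> None:
        if self.larvae is None and self.counts is None:
            raise ValueError("need larvae or genotype counts")
        if self.larvae is not None:
            derived: dict[str, GenotypeCounts] = {arm: {} for arm in ARMS}
            for larva in self.larvae:
                for arm in ARMS:
                    key = larva.genotypes[arm].key
                    derived[arm][key] = derived[arm].get(key, 0) + 1
            if self.counts is None:
                self.counts = derived
            self.b_carriers = sum(
                1 for larva in self.larvae if larva.b_chromosomes > 0
            )
        ns = {sum(c.values()) for c in self.counts.values() if c}
        if len(ns) > 1:
            raise ValueError(f"{self.code}: per-arm counts disagree: {ns}")
        if not ns or ns == {0}:
            raise ValueError(f"{self.code}: empty sample")
        self.n = ns.pop()


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Per-arm banding-sequence frequency vectors for one population."""

    population: str
    freqs: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for arm, vec in self.freqs.items():
            total = sum(vec.values())
            if vec and abs(total - 1.0) > 2e-3:  # printed-rounding tolerance
                raise ValueError(
                    f"{self.population} arm {arm}: frequencies sum to {total}"
                )
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"{self.population} arm {arm}: negative frequency")

    @property
    def arms(self) -> list[str]:
        return sorted(self.freqs)

    def frequency(self, arm: str, seq_id: str) -> float:
        return self.freqs[arm].get(seq_id, 0.0)

    def nonzero_ids(self, arm: str | None = None) -> set[str]:
        arms = [arm] if arm else self.arms
        return {
            s for a in arms for s, f in self.freqs[a].items() if f > 0
        }


@dataclass(frozen=True)
class PolymorphismSummary:
    """Per-population indices of chromosomal polymorphism."""

    population: str
    n: int
    pct_het_larvae: float
    het_inv_per_larva: float
    n_sequences: int
    n_genotypes: int
    b_chromosome_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_het_larvae <= 100.0:
            raise ValueError("pct_het_larvae outside [0, 100]")
        if self.het_inv_per_larva < 0:
            raise ValueError("negative inversion index")


@dataclass(frozen=True)
class HWTestResult:
    """Chi-square goodness of fit of one arm's genotypes to HW proportions."""

    arm: str
    n: int
    observed: Mapping[tuple[str, str], int]
    expected: Mapping[tuple[str, str], float]
    chi_square: float
    df: int
    p_value: float
    direction: str

    @property
    def tested(self) -> bool:
        return self.df > 0


def allele_frequencies(sample: PopulationSample) -> AlleleFrequencyTable:
    """Per-arm allele frequencies: p_i = f(ii) + sum_j f(ij)/2.

    Computed in exact rational arithmetic on allele-copy counts before
    conversion to float, so each arm's vector sums to one exactly.
    """
    freqs: dict[str, dict[str, float]] = {}
    for arm, counts in sample.counts.items():
        if not counts:
            continue
        copies: Counter[str] = Counter()
        for (a, b), c in counts.items():
            copies[a] += c
            copies[b] += c
        total = sum(copies.values())
        freqs[arm] = {
            s: float(Fraction(c, total)) for s, c in sorted(copies.items())
        }
    return AlleleFrequencyTable(sample.code, freqs)


def polymorphism_summary(
    sample: PopulationSample, allow_counts: bool = False
) -> PolymorphismSummary:
    """Summary indices for one population.

    Needs larva-level data for the exact heterozygosity indices.  With
    ``allow_counts=True`` aggregated genotype counts are accepted and the
    percent-heterozygous index is computed under the assumption that
    arms assort independently within larvae.
    """
    seq_ids = {
        s
        for counts in sample.counts.values()
        for key in counts
        for s in key
    }
    n_genotypes = sum(len(c) for c in sample.counts.values())
    n = sample.n
    if sample.larvae is not None:
        het_larvae = sum(1 for l in sample.larvae if l.heterozygous_arms)
        het_arms = sum(len(l.heterozygous_arms) for l in sample.larvae)
        pct = 100.0 * het_larvae / n
        per_larva = het_arms / n
    elif allow_counts:
        het_share = []
        for counts in sample.counts.values():
            het = sum(c for key, c in counts.items() if key[0] != key[1])
            het_share.append(het / n)
        pct = 100.0 * (1.0 - math.prod(1.0 - h for h in het_share))
        per_larva = sum(het_share)
    else:
        raise ValueError(
            "larva-level data required (pass allow_counts=True to accept "
            "aggregated counts under the arm-independence assumption)"
        )
    b_freq = (sample.b_carriers or 0) / n
    return PolymorphismSummary(
        population=sample.code,
        n=n,
        pct_het_larvae=pct,
        het_inv_per_larva=per_larva,
        n_sequences=len({sequence_key(s) for s in seq_ids}),
        n_genotypes=n_genotypes,
        b_chromosome_freq=b_freq,
    )


def quantitative_panel_means(
    summaries: Sequence[PolymorphismSummary],
) -> tuple[float, float]:
    """Unweighted means of the two polymorphism indices across a panel.

    The panel is the set of populations large enough for quantitative
    analysis (more than 10 specimens).
    """
    if not summaries:
        raise ValueError("empty panel")
    pct = sum(s.pct_het_larvae for s in summaries) / len(summaries)
    inv = sum(s.het_inv_per_larva for s in summaries) / len(summaries)
    return pct, inv


def hw_expected(freqs: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """Hardy-Weinberg genotype proportions: E(ii)=p_i^2, E(ij)=2 p_i p_j."""
    total = sum(freqs.values())
    if abs(total - 1.0) > 2e-3:
        raise ValueError(f"allele frequencies sum to {total}, expected 1")
    if any(p < 0 for p in freqs.values()):
        raise ValueError("negative allele frequency")
    ids = sorted(freqs, key=_serial)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations_with_replacement(ids, 2):
        p, q = freqs[a], freqs[b]
        out[(a, b)] = p * p if a == b else 2 * p * q
    return out


def _split_counts(
    counts: Mapping[tuple[str, str], int]
) -> tuple[int, dict[str, int]]:
    n = sum(counts.values())
    copies: Counter[str] = Counter()
    for (a, b), c in counts.items():
        copies[a] += c
        copies[b] += c
    return n, dict(copies)


def hw_chi_square(
    counts: Mapping[tuple[str, str], int], arm: str | None = None
) -> HWTestResult:
    """Chi-square test of one arm's genotype counts against HW.

    Alleles are those observed in the counts; df = k(k+1)/2 - k.  Classes
    expected and observed to be empty are dropped from the sum; an empty
    expectation with a non-empty observation is a degenerate input.  The
    deviation direction is the sign of (observed - expected) total
    heterozygote frequency.
    """
    counts = {
        tuple(sorted(g, key=_serial)): c for g, c in counts.items()
    }
    n, copies = _split_counts(counts)
    if n < 1:
        raise ValueError("empty genotype counts")
    if arm is None:
        arm = _arm_of(next(iter(counts))[0])
    k = len(copies)
    freqs = {s: c / (2 * n) for s, c in copies.items()}
    expected_freq = hw_expected(freqs)
    expected = {g: n * p for g, p in expected_freq.items()}
    df = k * (k + 1) // 2 - k
    if df == 0:
        return HWTestResult(arm, n, dict(counts), expected, 0.0, 0, 1.0, NO_DEVIATION)
    chi = 0.0
    for g, e in expected.items():
        o = counts.get(tuple(sorted(g, key=_serial)), 0)
        if e == 0:
            if o > 0:
                raise ValueError(f"genotype {g} observed but expectation is zero")
            continue
        chi += (o - e) ** 2 / e
    p_value = float(stats.chi2.sf(chi, df))
    obs_het = sum(c for (a, b), c in counts.items() if a != b) / n
    exp_het = sum(p for (a, b), p in expected_freq.items() if a != b)
    if math.isclose(obs_het, exp_het, abs_tol=1e-12) or p_value >= 1.0:
        direction = NO_DEVIATION
    else:
        direction = HET_EXCESS if obs_het > exp_het else HET_DEFICIT
    return HWTestResult(
        arm, n, dict(counts), expected, chi, df, p_value, direction
    )


def hw_exact_test(counts: Mapping[tuple[str, str], int]) -> float:
    """Conditional exact HW test by complete enumeration (n <= 50).

    Enumerates every genotype array compatible with the observed allele
    counts; the p-value is the total probability of arrays no more
    probable than the observed one under the Levene conditional
    distribution P(array) ∝ 2^h * n! / prod(a_ij!).
    """
    counts = {
        tuple(sorted(g, key=_serial)): c for g, c in counts.items()
    }
    n, copies = _split_counts(counts)
    if n > 50:
        raise ValueError("exact test restricted to n <= 50")
    alleles = sorted(copies, key=_serial)
    pairs = list(combinations_with_replacement(alleles, 2))

    def log_weight(array: dict[tuple[str, str], int]) -> float:
        h = sum(c for (a, b), c in array.items() if a != b)
        lw = h * math.log(2.0) + math.lgamma(n + 1)
        for c in array.values():
            lw -= math.lgamma(c + 1)
        return lw

    observed = {
        p: counts.get(p, 0) for p in pairs
    }
    arrays: list[dict[tuple[str, str], int]] = []

    def recurse(idx: int, remaining: dict[str, int], used: int, partial: dict):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()) and used == n:
                arrays.append(dict(partial))
            return
        a, b = pairs[idx]
        if a == b:
            cap = min(remaining[a] // 2, n - used)
        else:
            cap = min(remaining[a], remaining[b], n - used)
        for c in range(cap + 1):
            remaining[a] -= c * (2 if a == b else 1)
            if a != b:
                remaining[b] -= c
            partial[(a, b)] = c
            recurse(idx + 1, remaining, used + c, partial)
            remaining[a] += c * (2 if a == b else 1)
            if a != b:
                remaining[b] += c
        del partial[(a, b)]

    recurse(0, dict(copies), 0, {})
    log_ws = [log_weight(arr) for arr in arrays]
    m = max(log_ws)
    weights = [math.exp(lw - m) for lw in log_ws]
    total = sum(weights)
    w_obs = math.exp(log_weight(observed) - m)
    p = sum(w for w in weights if w <= w_obs * (1 + 1e-12)) / total
    return min(1.0, p)


@dataclass(frozen=True)
class PoolCensus:
    """Distinct banding sequences pooled over populations."""

    pool_size: int
    per_population: dict[str, int]


def pool_census(tables: Sequence[AlleleFrequencyTable]) -> PoolCensus:
    """Count distinct sequences with nonzero frequency anywhere.

    Sequences are identified by (species, arm, serial) so that the same
    sequence written with different distribution prefixes is counted
    once.
    """
    if not tables:
        raise ValueError("need at least one frequency table")
    pooled: set[tuple[str, str, int]] = set()
    per_pop: dict[str, int] = {}
    for t in tables:
        ids = {sequence_key(s) for s in t.nonzero_ids()}
        per_pop[t.population] = len(ids)
        pooled |= ids
    return PoolCensus(len(pooled), per_pop)
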
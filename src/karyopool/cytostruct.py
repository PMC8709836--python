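"""Cytogenetic-structure typing of populations.

A population's cytogenetic structure type is "0" when the main
(serial-1) banding sequence holds a strict majority in every arm, and
otherwise the sorted letters of the arms in which an alternative
sequence dominates (e.g. type "B" when sequence 2 of arm B is the
majority allele).  "Dominant" is read as strict majority (> 0.5), which
is well defined even for three-allele arms; an arm with no strict
majority is flagged mixed and excluded from the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .bandmap import ARMS, parse_sequence_id
from .popstats import AlleleFrequencyTable

__all__ = ["StructureType", "classify_structure", "polygon_vectors"]


@dataclass(frozen=True)
class StructureType:
    """Population structure label plus per-arm detail."""

    label: str
    dominant: Mapping[str, str | None]  # arm -> majority sequence id (or None)
    mixed_arms: tuple[str, ...] = ()

    def __str__(self) -> str:
        return self.label


def _serial(seq_id: str) -> int:
    return parse_sequence_id(seq_id)[3]


def classify_structure(table: AlleleFrequencyTable) -> StructureType:
    """Type a population from its per-arm sequence frequencies."""
    missing = [arm for arm in ARMS if arm not in table.freqs]
    if missing:
        raise ValueError(f"{table.population}: missing arms {missing}")
    letters: list[str] = []
    dominant: dict[str, str | None] = {}
    mixed: list[str] = []
    for arm in ARMS:
        vec = table.freqs[arm]
        winner = max(vec, key=lambda s: (vec[s], -_serial(s)), default=None)
        if winner is None or vec[winner] <= 0.5:
            dominant[arm] = None
            mixed.append(arm)
            continue
        dominant[arm] = winner
        if _serial(winner) != 1:
            letters.append(arm)
    label = "".join(sorted(set(letters))) or "0"
    return StructureType(label, dominant, tuple(mixed))


def polygon_vectors(table: AlleleFrequencyTable) -> dict[str, float]:
    """Main-sequence (serial-1) frequency per arm A..G, for polygon plots."""
    missing = [arm for arm in ARMS if arm not in table.freqs]
    if missing:
        raise ValueError(f"{table.population}: missing arms {missing}")
    out: dict[str, float] = {}
    for arm in ARMS:
        vec = table.freqs[arm]
        out[arm] = sum(f for s, f in vec.items() if _serial(s) == 1)
    return out
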
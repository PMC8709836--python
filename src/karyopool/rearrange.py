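"""Reversal distances between banding sequences of one arm.

Two banding sequences of an arm are band-set permutations of each other;
after projecting onto their common segment refinement the comparison
becomes sorting a signed permutation by reversals.  The pools this
package targets are small (a handful of inversions per arm), so the
distance is computed exactly by iterative-deepening exhaustive search
with breakpoint-count pruning rather than Hannenhalli-Pevzner machinery.

The centromere is a fixed terminal marker and never takes part in a
reversal: every inversion modelled here is paracentric.

Orientation of a single-band segment is not expressible in the listing
notation; such segments carry a free sign which the search minimises
over, so the reported distance is the smallest over all orientation
assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import ceil

from .bandmap import (
    ASCENDING,
    SINGLETON,
    BandLabel,
    BandMapError,
    Refinement,
    SequenceMap,
    common_refinement,
)

__all__ = [
    "SignedArrangement",
    "RearrangementResult",
    "to_signed_arrangement",
    "reversal_distance",
    "apply_scenario",
    "single_reversal_breakpoints",
    "classify_pair",
    "compare_maps",
]

IDENTICAL = "identical"
SIMPLE = "simple"
COMPLEX = "complex"


@dataclass(frozen=True)
class SignedArrangement:
    """A signed permutation of segment ids 1..n with an ambiguity mask.

    ``values[i]`` is the reference position of the i-th segment in the
    target's traversal, signed by relative orientation.  Positions listed
    in ``ambiguous`` (0-based indices into ``values``) have a free sign:
    the notation leaves the orientation of a single-band segment open.
    """

    values: tuple[int, ...]
    ambiguous: frozenset[int] = frozenset()
    refinement: Refinement | None = None

    def __post_init__(self) -> None:
        n = len(self.values)
        if sorted(abs(v) for v in self.values) != list(range(1, n + 1)):
            raise ValueError("values must be a signed permutation of 1..n")
        if any(i < 0 or i >= n for i in self.ambiguous):
            raise ValueError("ambiguity mask outside the arrangement")

    @property
    def n(self) -> int:
        return len(self.values)

    def assignments(self):
        """Iterate concrete sign assignments for the ambiguous positions."""
        amb = sorted(self.ambiguous)
        base = list(self.values)
        for signs in itertools.product((1, -1), repeat=len(amb)):
            perm = base[:]
            for i, s in zip(amb, signs):
                perm[i] = s * abs(perm[i])
            yield tuple(perm)


@dataclass(frozen=True)
class RearrangementResult:
    """Distance, witness scenario and simple/complex call for one pair.

    ``scenario`` is a list of 1-based inclusive position intervals; each
    reversal acts on the current arrangement, starting from the
    reference, and the full list transforms reference into target.  When
    ``exact`` is False the search was cut off and ``distance`` is only
    the breakpoint lower bound.
    """

    distance: int
    scenario: tuple[tuple[int, int], ...] | None
    classification: str
    exact: bool = True

    @property
    def unresolved(self) -> bool:
        return not self.exact


def to_signed_arrangement(
    target: SequenceMap, reference: SequenceMap
) -> SignedArrangement:
    """Express ``target`` as a signed permutation relative to ``reference``.

    Built on the common segment refinement: the reference reads as the
    identity ``+1..+n`` and the target's traversal supplies the signed
    arrangement.  Segments covered by a single-band run in either map are
    flagged ambiguous.
    """
    ref = common_refinement(reference, target)
    pos = {seg: k + 1 for k, (seg, _d) in enumerate(ref.a_order)}
    dir_a = {seg: d for seg, d in ref.a_order}
    values: list[int] = []
    ambiguous: set[int] = set()
    for i, (seg, d_b) in enumerate(ref.b_order):
        d_a = dir_a[seg]
        if d_a == SINGLETON or d_b == SINGLETON:
            values.append(pos[seg])
            ambiguous.add(i)
        else:
            values.append(pos[seg] if d_a == d_b else -pos[seg])
    return SignedArrangement(tuple(values), frozenset(ambiguous), ref)


def _breakpoints(ext: list[int]) -> int:
    return sum(
        1 for i in range(len(ext) - 1) if ext[i + 1] - ext[i] != 1
    )


def _invert(perm: tuple[int, ...]) -> list[int]:
    inv = [0] * len(perm)
    for i, v in enumerate(perm, start=1):
        inv[abs(v) - 1] = i if v > 0 else -i
    return inv


def _sort_moves(
    perm: tuple[int, ...], max_d: int
) -> tuple[int, list[tuple[int, int]] | None]:
    """Minimal reversal scenario sorting ``perm`` to the identity.

    Iterative-deepening DFS over all contiguous reversals; a node is cut
    when ceil(breakpoints/2) exceeds the remaining budget (a reversal
    mends at most two breakpoints).  Intervals are tried in ascending
    (start, end) order, so the first scenario found is the
    lexicographically smallest among the minimal ones.  Returns
    ``(lower_bound, None)`` if no scenario within ``max_d`` exists.
    """
    n = len(perm)
    ext = [0, *perm, n + 1]
    bp0 = _breakpoints(ext)
    lb0 = ceil(bp0 / 2)
    if bp0 == 0:
        return 0, []
    moves: list[tuple[int, int]] = []

    def dfs(bp: int, remaining: int) -> bool:
        if bp == 0:
            return True
        if ceil(bp / 2) > remaining:
            return False
        # reversal of ext[i..j] (1-based inclusive over permutation slots)
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                left_old = 0 if ext[i] - ext[i - 1] == 1 else 1
                right_old = 0 if ext[j + 1] - ext[j] == 1 else 1
                left_new = 0 if -ext[j] - ext[i - 1] == 1 else 1
                right_new = 0 if ext[j + 1] + ext[i] == 1 else 1
                bp_new = bp - left_old - right_old + left_new + right_new
                if ceil(bp_new / 2) > remaining - 1:
                    continue
                ext[i : j + 1] = [-v for v in reversed(ext[i : j + 1])]
                moves.append((i, j))
                if dfs(bp_new, remaining - 1):
                    return True
                moves.pop()
                ext[i : j + 1] = [-v for v in reversed(ext[i : j + 1])]
        return False

    for limit in range(lb0, max_d + 1):
        if dfs(bp0, limit):
            return len(moves), moves
    return lb0, None


def reversal_distance(
    arr: SignedArrangement, max_d: int = 3
) -> RearrangementResult:
    """Exact minimal reversal count from the reference to ``arr``.

    Minimised over all assignments of the ambiguous signs.  Beyond
    ``max_d`` the breakpoint lower bound is returned with the result
    flagged unresolved.
    """
    best_d: int | None = None
    best_moves: list[tuple[int, int]] | None = None
    best_lb = None
    for perm in arr.assignments():
        # Sorting the inverse permutation with moves tried in (start, end)
        # order yields the reference-to-target scenario directly: a
        # positional reversal on the evolving arrangement is the same
        # positional reversal on its composition with a fixed relabeling.
        inv = tuple(_invert(perm))
        d, mv = _sort_moves(inv, max_d)
        if mv is None:
            best_lb = d if best_lb is None else min(best_lb, d)
            continue
        if best_d is None or d < best_d or (d == best_d and mv < best_moves):
            best_d, best_moves = d, mv
    if best_d is None:
        lb = best_lb if best_lb is not None else 0
        return RearrangementResult(lb, None, COMPLEX if lb >= 2 else SIMPLE, exact=False)
    cls = IDENTICAL if best_d == 0 else SIMPLE if best_d == 1 else COMPLEX
    return RearrangementResult(best_d, tuple(best_moves), cls, exact=True)


def apply_scenario(
    scenario: tuple[tuple[int, int], ...], n: int
) -> list[int]:
    """Apply a scenario to the identity ``+1..+n``; returns the result."""
    state = list(range(1, n + 1))
    for i, j in scenario:
        if not (1 <= i <= j <= n):
            raise ValueError(f"reversal ({i},{j}) outside 1..{n}")
        state[i - 1 : j] = [-v for v in reversed(state[i - 1 : j])]
    return state


def compare_maps(
    a: SequenceMap, b: SequenceMap, max_d: int = 3
) -> tuple[SignedArrangement, RearrangementResult]:
    arr = to_signed_arrangement(b, reference=a)
    return arr, reversal_distance(arr, max_d=max_d)


def single_reversal_breakpoints(
    a: SequenceMap, b: SequenceMap, max_d: int = 3
) -> tuple[BandLabel, BandLabel] | None:
    """Endpoints of the inverted band interval when the pair differs by
    exactly one reversal; None otherwise.

    Endpoints are the first and last band of the reversed block in the
    reference map ``a``.
    """
    arr, result = compare_maps(a, b, max_d=max_d)
    if not result.exact or result.distance != 1:
        return None
    (i, j) = result.scenario[0]
    ref = arr.refinement
    seg_i, dir_i = ref.a_order[i - 1]
    seg_j, dir_j = ref.a_order[j - 1]
    first = ref.segments[seg_i][-1 if dir_i == -1 else 0]
    last = ref.segments[seg_j][0 if dir_j == -1 else -1]
    return first, last


def classify_pair(a: SequenceMap, b: SequenceMap, max_d: int = 3) -> str:
    """identical / simple / complex call for a pair of maps of one arm."""
    _arr, result = compare_maps(a, b, max_d=max_d)
    return result.classification
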
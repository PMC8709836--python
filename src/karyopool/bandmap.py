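"""Parsing and algebra of polytene-chromosome banding-sequence maps.

A banding sequence is the linear order of bands along one polytene
chromosome arm, written as a list of *runs*.  Each run is a stretch of
bands that is contiguous in the reference (standard) band order, given by
its two endpoint band labels, e.g. ``25s-q`` (descending within section
25), ``18n-16a`` (descending across sections), ``22ab`` (two adjacent
lettered bands, fused token), or ``3i`` (a single band).  A listing ends
with the centromere marker ``C``.  Alternative sequences of the same arm
are permutations of one band set related by paracentric inversions.

Band coordinates are section numbers subdivided by lowercase letters.
The band universe of an arm is never declared explicitly; it is inferred
from the pool of listings (`infer_catalogue`): a section carries letters
``a..max`` where *max* is the highest letter ever written for it, and a
section that is only ever swept through inside a cross-section range is a
single atomic unit.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Sequence

ARMS = "ABCDEFG"

ASCENDING = 1
DESCENDING = -1
SINGLETON = 0

__all__ = [
    "ARMS",
    "ASCENDING",
    "DESCENDING",
    "SINGLETON",
    "BandMapError",
    "ParseError",
    "CatalogueError",
    "BandLabel",
    "BandRun",
    "SequenceMap",
    "ArmCatalogue",
    "Refinement",
    "ValidationReport",
    "parse_sequence_id",
    "parse_sequence_line",
    "format_sequence_line",
    "infer_catalogue",
    "expand_map",
    "validate_arm_pool",
    "common_refinement",
    "read_pool",
    "write_pool",
]


class BandMapError(ValueError):
    """Base error for banding-map parsing and algebra."""


class ParseError(BandMapError):
    """A listing line or token could not be parsed."""


class CatalogueError(BandMapError):
    """Inconsistent evidence about an arm's band universe."""


@total_ordering
@dataclass(frozen=True)
class BandLabel:
    """One band coordinate: a section number plus an optional letter.

    ``letter is None`` denotes a whole section treated as a single atomic
    band.  Canonical order is lexicographic on ``(section, letter)`` with
    the atomic form ordered as a whole-section unit.
    """

    section: int
    letter: str | None = None

    def __post_init__(self) -> None:
        if self.section < 1:
            raise BandMapError(f"section must be >= 1, got {self.section}")
        if self.letter is not None and (
            len(self.letter) != 1 or not "a" <= self.letter <= "z"
        ):
            raise BandMapError(f"bad band letter {self.letter!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.section, self.letter or "")

    def __lt__(self, other: "BandLabel") -> bool:
        return self.key < other.key

    def __str__(self) -> str:
        return f"{self.section}{self.letter or ''}"


@dataclass(frozen=True)
class BandRun:
    """A maximal stretch of reference-contiguous bands in a listing.

    ``fused`` records the source spelling of two-band same-section runs
    (``22ab`` rather than ``22a-b``) so that formatting round-trips.
    """

    start: BandLabel
    end: BandLabel
    fused: bool = False

    @property
    def direction(self) -> int:
        if self.start == self.end:
            return SINGLETON
        return ASCENDING if self.start < self.end else DESCENDING

    def reversed_(self) -> "BandRun":
        return BandRun(self.end, self.start, fused=self.fused)

    def __str__(self) -> str:
        return format_run(self)


@dataclass(frozen=True)
class SequenceMap:
    """One named banding sequence of one arm.

    The id encodes a geographic-distribution prefix (``p'`` Palearctic,
    ``h'`` Holarctic), a species tag (``agi``), the arm letter and the
    serial number of the sequence within the arm.  ``runs is None`` marks
    a sequence that is catalogued but not band-mapped (arm G).
    """

    prefix: str
    species: str
    arm: str
    serial: int
    runs: tuple[BandRun, ...] | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise BandMapError(f"unknown arm {self.arm!r}")
        if self.runs is not None and len(self.runs) == 0:
            raise BandMapError("a mapped sequence needs at least one run")

    @property
    def name(self) -> str:
        return f"{self.prefix}'{self.species}{self.arm}{self.serial}"

    @property
    def mapped(self) -> bool:
        return self.runs is not None

    def __str__(self) -> str:
        return self.name


_ID_RE = re.compile(r"^([a-z])['’]([a-z]+)([A-G])(\d+)$")
# token shapes: "22a-r" | "18n-16a" | "15f-12v" | "13-15" | "22ab" | "3i" | "14"
_WITHIN_RE = re.compile(r"^(\d+)([a-z])-([a-z])$")
_CROSS_RE = re.compile(r"^(\d+)([a-z]?)-(\d+)([a-z]?)$")
_PLAIN_RE = re.compile(r"^(\d+)([a-z]{0,2})$")


def parse_sequence_id(token: str) -> tuple[str, str, str, int]:
    """Split an id like ``p'agiB1`` into (prefix, species, arm, serial)."""
    m = _ID_RE.match(token)
    if not m:
        raise ParseError(f"malformed sequence id {token!r}")
    prefix, species, arm, serial = m.groups()
    return prefix, species, arm, int(serial)


def _parse_run(token: str) -> BandRun:
    m = _WITHIN_RE.match(token)
    if m:
        section = int(m.group(1))
        return BandRun(
            BandLabel(section, m.group(2)), BandLabel(section, m.group(3))
        )
    m = _CROSS_RE.match(token)
    if m:
        s1, l1, s2, l2 = m.groups()
        return BandRun(
            BandLabel(int(s1), l1 or None), BandLabel(int(s2), l2 or None)
        )
    m = _PLAIN_RE.match(token)
    if m:
        section = int(m.group(1))
        letters = m.group(2)
        if len(letters) <= 1:
            label = BandLabel(section, letters or None)
            return BandRun(label, label)
        # fused two-letter token: the letters must be adjacent in the alphabet
        a, b = letters
        if abs(ord(a) - ord(b)) != 1:
            raise ParseError(
                f"fused token {token!r}: letters {a!r},{b!r} are not adjacent"
            )
        return BandRun(BandLabel(section, a), BandLabel(section, b), fused=True)
    raise ParseError(f"unparseable run token {token!r}")


def parse_sequence_line(text: str) -> SequenceMap:
    """Parse one listing line, e.g. ``p'agiB1 25s-q ... 15f-12v C``."""
    tokens = text.split()
    if not tokens:
        raise ParseError("empty listing line")
    prefix, species, arm, serial = parse_sequence_id(tokens[0])
    if len(tokens) < 2:
        raise ParseError(f"{tokens[0]}: listing has no run tokens")
    if tokens[-1] != "C":
        raise ParseError(f"{tokens[0]}: missing terminal centromere marker 'C'")
    body = tokens[1:-1]
    if not body:
        raise ParseError(f"{tokens[0]}: no run tokens before the centromere")
    if "C" in body:
        raise ParseError(f"{tokens[0]}: centromere marker must be terminal")
    runs = tuple(_parse_run(tok) for tok in body)
    return SequenceMap(prefix, species, arm, serial, runs)


def format_run(run: BandRun, fused_dialect: bool = True) -> str:
    s, e = run.start, run.end
    if s == e:
        return str(s)
    if s.section == e.section:
        if (
            run.fused
            and fused_dialect
            and s.letter
            and e.letter
            and abs(ord(s.letter) - ord(e.letter)) == 1
        ):
            return f"{s.section}{s.letter}{e.letter}"
        return f"{s}-{e.letter}"
    return f"{s}-{e}"


def format_sequence_line(m: SequenceMap, fused_dialect: bool = True) -> str:
    """Render a map back to its listing line; inverse of parsing."""
    if not m.mapped:
        raise BandMapError(f"{m.name} is not band-mapped")
    body = " ".join(format_run(r, fused_dialect) for r in m.runs)
    return f"{m.name} {body} C"


@dataclass(frozen=True)
class ArmCatalogue:
    """The inferred band universe of one arm, in canonical physical order."""

    arm: str
    bands: tuple[BandLabel, ...]

    def __post_init__(self) -> None:
        if list(self.bands) != sorted(self.bands):
            raise CatalogueError("catalogue bands must be in canonical order")
        if len(set(self.bands)) != len(self.bands):
            raise CatalogueError("duplicate bands in catalogue")

    @property
    def index(self) -> dict[BandLabel, int]:
        return {b: i for i, b in enumerate(self.bands)}

    def letter_count(self, section: int) -> int | None:
        """Number of lettered subdivisions of a section; None if atomic."""
        letters = [b.letter for b in self.bands if b.section == section]
        if not letters:
            raise KeyError(section)
        if letters == [None]:
            return None
        return len(letters)

    def __len__(self) -> int:
        return len(self.bands)


def infer_catalogue(maps: Sequence[SequenceMap]) -> ArmCatalogue:
    """Infer the band universe of an arm from all of its listings.

    A section named with a letter anywhere carries letters ``a..max``
    observed; a section referenced only implicitly (inside a
    cross-section range) is a single atomic unit.  A section written both
    bare (atomic) and lettered is conflicting evidence.
    """
    mapped = [m for m in maps if m.mapped]
    if not mapped:
        raise CatalogueError("need at least one mapped sequence")
    arms = {m.arm for m in mapped}
    if len(arms) != 1:
        raise CatalogueError(f"maps from multiple arms: {sorted(arms)}")
    (arm,) = arms

    letter_max: dict[int, str] = {}
    atomic_explicit: set[int] = set()
    interior: set[int] = set()
    for m in mapped:
        for run in m.runs:
            for label in (run.start, run.end):
                if label.letter is None:
                    atomic_explicit.add(label.section)
                else:
                    prev = letter_max.get(label.section, "a")
                    letter_max[label.section] = max(prev, label.letter)
            lo = min(run.start.section, run.end.section)
            hi = max(run.start.section, run.end.section)
            interior.update(range(lo + 1, hi))

    conflict = atomic_explicit & set(letter_max)
    if conflict:
        raise CatalogueError(
            f"arm {arm}: sections both atomic and lettered: {sorted(conflict)}"
        )
    sections = sorted(set(letter_max) | atomic_explicit | interior)
    bands: list[BandLabel] = []
    for s in sections:
        if s in letter_max:
            for code in range(ord("a"), ord(letter_max[s]) + 1):
                bands.append(BandLabel(s, chr(code)))
        else:
            bands.append(BandLabel(s))
    # The arm's physical span is delimited by the extreme endpoint labels
    # ever written: a terminal section may enter the arm only from some
    # letter upward (e.g. an arm ending at 12v has no 12a..12u), so the
    # contiguity rule is clipped to the referenced span.
    endpoints = [
        lab
        for m in mapped
        for run in m.runs
        for lab in (run.start, run.end)
    ]
    lo, hi = min(endpoints), max(endpoints)
    bands = [b for b in bands if lo <= b <= hi]
    return ArmCatalogue(arm, tuple(bands))


def expand_map(
    m: SequenceMap, cat: ArmCatalogue
) -> list[tuple[BandLabel, int]]:
    """Expand a map into its full oriented band list.

    Each run becomes the canonical-order interval between its endpoints,
    emitted start-to-end; members of descending runs carry orientation
    ``-1``, ascending ``+1``.  A single band's orientation is not
    expressible in the notation and is emitted as ``0`` (ambiguous).
    """
    if not m.mapped:
        raise BandMapError(f"{m.name} is not band-mapped")
    index = cat.index
    out: list[tuple[BandLabel, int]] = []
    for run in m.runs:
        try:
            i = index[run.start]
            j = index[run.end]
        except KeyError as exc:
            raise BandMapError(
                f"{m.name}: run endpoint {exc.args[0]} not in arm catalogue"
            ) from None
        if i == j:
            out.append((cat.bands[i], SINGLETON))
        elif i < j:
            out.extend((b, ASCENDING) for b in cat.bands[i : j + 1])
        else:
            out.extend((b, DESCENDING) for b in reversed(cat.bands[j : i + 1]))
    return out


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking that an arm's listings are band-set permutations."""

    arm: str
    catalogue: ArmCatalogue
    ok: bool
    missing: dict[str, tuple[BandLabel, ...]]
    extra: dict[str, tuple[BandLabel, ...]]

    def message(self) -> str:
        if self.ok:
            return f"arm {self.arm}: all listings are permutations of one band set"
        lines = [f"arm {self.arm}: band multisets differ between listings"]
        for name in sorted(set(self.missing) | set(self.extra)):
            miss = ", ".join(map(str, self.missing.get(name, ())))
            ext = ", ".join(map(str, self.extra.get(name, ())))
            lines.append(f"  {name}: missing [{miss}] extra [{ext}]")
        return "\n".join(lines)


def validate_arm_pool(maps: Sequence[SequenceMap]) -> ValidationReport:
    """Check that every mapped listing of one arm covers the same band set."""
    cat = infer_catalogue(maps)
    reference = Counter(cat.bands)
    missing: dict[str, tuple[BandLabel, ...]] = {}
    extra: dict[str, tuple[BandLabel, ...]] = {}
    for m in maps:
        if not m.mapped:
            continue
        observed = Counter(b for b, _sign in expand_map(m, cat))
        miss = reference - observed
        ext = observed - reference
        if miss or ext:
            missing[m.name] = tuple(sorted(miss.elements()))
            extra[m.name] = tuple(sorted(ext.elements()))
    ok = not missing and not extra
    return ValidationReport(cat.arm, cat, ok, missing, extra)


@dataclass(frozen=True)
class Refinement:
    """Common refinement of two maps of one arm into shared segments.

    Segments are the maximal canonical band intervals never split by a
    run boundary of either map.  ``a_order``/``b_order`` give each map's
    traversal as ``(segment index, direction)`` pairs, direction being
    the run direction (0 for single-band, direction-ambiguous runs).
    """

    catalogue: ArmCatalogue
    segments: tuple[tuple[BandLabel, ...], ...]
    a_order: tuple[tuple[int, int], ...]
    b_order: tuple[tuple[int, int], ...]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_strings(self) -> tuple[str, str]:
        """Render both maps over the shared segment alphabet.

        The first map reads as the identity ``+1 +2 ... +n``; the second
        as a signed arrangement of the same ids (``?`` marks a segment
        whose orientation the notation leaves free).
        """
        pos = {seg: k + 1 for k, (seg, _d) in enumerate(self.a_order)}
        dir_a = {seg: d for seg, d in self.a_order}
        a_str = " ".join(f"+{k}" for k in range(1, self.n_segments + 1))
        parts = []
        for seg, d in self.b_order:
            if d == SINGLETON or dir_a[seg] == SINGLETON:
                parts.append(f"?{pos[seg]}")
            else:
                parts.append(f"{'+' if d == dir_a[seg] else '-'}{pos[seg]}")
        return a_str, " ".join(parts)


def _traverse_segments(
    m: SequenceMap,
    cat: ArmCatalogue,
    seg_of_start: dict[int, int],
    seg_span: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    index = cat.index
    order: list[tuple[int, int]] = []
    for run in m.runs:
        i, j = index[run.start], index[run.end]
        lo, hi = min(i, j), max(i, j)
        k = seg_of_start[lo]
        covered = []
        while seg_span[k][0] <= hi:
            covered.append(k)
            k += 1
            if k == len(seg_span):
                break
        if seg_span[covered[-1]][1] != hi:
            raise BandMapError(
                f"{m.name}: run {run} does not align with segment boundaries"
            )
        d = run.direction
        if d == DESCENDING:
            covered.reverse()
        order.extend((seg, d) for seg in covered)
    return order


def common_refinement(a: SequenceMap, b: SequenceMap) -> Refinement:
    """Refine two maps of one arm onto a shared segment alphabet.

    Requires the pair to be band-set permutations of each other (their
    joint catalogue); raises `BandMapError` otherwise.
    """
    if a.arm != b.arm:
        raise BandMapError(f"maps of different arms: {a.arm} vs {b.arm}")
    report = validate_arm_pool([a, b])
    if not report.ok:
        raise BandMapError(report.message())
    cat = report.catalogue
    index = cat.index
    n = len(cat)

    cuts: set[int] = {0, n}
    for m in (a, b):
        for run in m.runs:
            i, j = index[run.start], index[run.end]
            cuts.add(min(i, j))
            cuts.add(max(i, j) + 1)
    edges = sorted(cuts)
    seg_span = [(edges[k], edges[k + 1] - 1) for k in range(len(edges) - 1)]
    segments = tuple(
        tuple(cat.bands[lo : hi + 1]) for lo, hi in seg_span
    )
    seg_of_start = {lo: k for k, (lo, _hi) in enumerate(seg_span)}

    a_order = _traverse_segments(a, cat, seg_of_start, seg_span)
    b_order = _traverse_segments(b, cat, seg_of_start, seg_span)
    for name, order in ((a.name, a_order), (b.name, b_order)):
        if sorted(seg for seg, _d in order) != list(range(len(segments))):
            raise BandMapError(f"{name}: traversal does not cover each segment once")
    return Refinement(cat, segments, tuple(a_order), tuple(b_order))


def read_pool(text: str) -> list[SequenceMap]:
    """Read a pool file: one listing per line, ``#`` comments.

    A line of the form ``<id> unmapped`` records a sequence that exists
    in the pool but has no published band map.
    """
    maps: list[SequenceMap] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            tokens = line.split()
            if len(tokens) == 2 and tokens[1] == "unmapped":
                prefix, species, arm, serial = parse_sequence_id(tokens[0])
                m = SequenceMap(prefix, species, arm, serial, None)
            else:
                m = parse_sequence_line(line)
        except BandMapError as exc:
            raise ParseError(f"pool line {lineno}: {exc}") from None
        if m.name in seen:
            raise ParseError(f"pool line {lineno}: duplicate id {m.name}")
        seen.add(m.name)
        maps.append(m)
    return maps


def write_pool(maps: Iterable[SequenceMap], fused_dialect: bool = True) -> str:
    lines = []
    for m in maps:
        if m.mapped:
            lines.append(format_sequence_line(m, fused_dialect))
        else:
            lines.append(f"{m.name} unmapped")
    return "\n".join(lines) + "\n"


def group_by_arm(maps: Iterable[SequenceMap]) -> dict[str, list[SequenceMap]]:
    out: dict[str, list[SequenceMap]] = {}
    for m in maps:
        out.setdefault(m.arm, []).append(m)
    return out
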
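"""Nei (1972) standard genetic distance and neighbor-joining trees.

Populations are compared over the seven chromosome arms, each arm
treated as one multi-allelic locus whose alleles are the banding
sequences.  The standard distance is

    I = J_XY / sqrt(J_X * J_Y),      D = -ln I,

where J_X, J_Y and J_XY are the arithmetic means *across loci* of
sum_i x_i^2, sum_i y_i^2 and sum_i x_i y_i.  Averaging the J terms
before forming I (rather than averaging per-locus identities) is Nei's
original definition; with it, shared monomorphic arms contribute 1 to
every J mean and pull I towards unity, so all seven arms always enter
the mean even when both populations are fixed on the same sequence.

Trees are built with the Saitou-Nei neighbor-joining agglomeration and
serialised as Newick via scikit-bio's ``TreeNode``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .bandmap import ARMS
from .popstats import AlleleFrequencyTable

__all__ = [
    "NeiResult",
    "nei_distance",
    "distance_matrix",
    "nj_tree",
    "write_newick",
    "read_newick",
    "read_phylip_matrix",
    "write_phylip_matrix",
    "round3",
]


def round3(x: float) -> float:
    """Round half-up to three decimals, as the source tables print."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class NeiResult:
    """Identity and distance between two populations, with the J terms."""

    j_x: float
    j_y: float
    j_xy: float

    @property
    def identity(self) -> float:
        # clamp guards rounding noise in printed frequencies from
        # producing I slightly above 1 (hence a negative distance)
        return min(1.0, self.j_xy / math.sqrt(self.j_x * self.j_y))

    @property
    def distance(self) -> float:
        return -math.log(self.identity)


def nei_distance(
    x: AlleleFrequencyTable,
    y: AlleleFrequencyTable,
    loci: Sequence[str] = tuple(ARMS),
) -> NeiResult:
    """Nei standard identity/distance over the given loci (arms)."""
    if not loci:
        raise ValueError("empty locus list")
    jx = jy = jxy = 0.0
    for arm in loci:
        if arm not in x.freqs or arm not in y.freqs:
            missing = arm if arm not in x.freqs else arm
            raise ValueError(f"locus {missing!r} missing from a frequency table")
        fx, fy = x.freqs[arm], y.freqs[arm]
        alleles = set(fx) | set(fy)
        jx += sum(fx.get(a, 0.0) ** 2 for a in alleles)
        jy += sum(fy.get(a, 0.0) ** 2 for a in alleles)
        jxy += sum(fx.get(a, 0.0) * fy.get(a, 0.0) for a in alleles)
    m = len(loci)
    return NeiResult(jx / m, jy / m, jxy / m)


def distance_matrix(
    tables: Sequence[AlleleFrequencyTable],
    loci: Sequence[str] = tuple(ARMS),
) -> DistanceMatrix:
    """Pairwise Nei D over a list of populations."""
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    codes = [t.population for t in tables]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate population codes")
    n = len(tables)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(tables[i], tables[j], loci).distance
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=codes)


def _pair_label(node: TreeNode) -> tuple[str, ...]:
    return tuple(sorted(t.name for t in node.tips())) if node.children else (node.name,)


def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising Q = (r-2) d_ij - R_i - R_j is merged at each
    step; ties are broken by the lexicographically smallest pair of
    cluster labels.  Negative branch lengths are clamped to zero.  The
    returned tree is unrooted (trifurcating root).
    """
    labels = list(m.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least three leaves")
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[(a, b)] = d[(b, a)] = float(m[a, b])
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in labels}
    active = sorted(labels)

    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * d[(a, b)] - row_sum[a] - row_sum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _q, a, b = best
        la = 0.5 * d[(a, b)] + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = d[(a, b)] - la
        la, lb = max(0.0, la), max(0.0, lb)
        nodes[a].length = la
        nodes[b].length = lb
        new_name = f"_nj{counter}"
        counter += 1
        nodes[new_name] = TreeNode(children=[nodes[a], nodes[b]])
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new_name, c)] = d[(c, new_name)] = dc
        active = sorted([c for c in active if c not in (a, b)] + [new_name])

    a, b, c = active
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    for name, length in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = max(0.0, length)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    if not text.strip():
        raise ValueError("empty Newick text")
    return TreeNode.read(io.StringIO(text), format="newick")


def write_phylip_matrix(m: DistanceMatrix, lower: bool = False) -> str:
    """Serialise a distance matrix; square or labelled lower triangle."""
    lines = [str(len(m.ids))]
    for i, name in enumerate(m.ids):
        stop = i if lower else len(m.ids)
        row = "\t".join(f"{float(m[name, other]):.3f}" for other in m.ids[:stop])
        lines.append(f"{name}\t{row}".rstrip())
    return "\n".join(lines) + "\n"


def read_phylip_matrix(text: str) -> DistanceMatrix:
    """Read a labelled distance matrix, full square or lower triangle.

    Accepts the dialect of printed distance tables: an optional leading
    count line, then one labelled row per population, the first row
    carrying no values when the triangle omits the diagonal.
    """
    rows: list[tuple[str, list[float]]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 1 and fields[0].isdigit() and not rows:
            continue  # PHYLIP count header
        rows.append((fields[0], [float(v) for v in fields[1:]]))
    if not rows:
        raise ValueError("no matrix rows found")
    labels = [name for name, _vals in rows]
    n = len(labels)
    lengths = [len(vals) for _name, vals in rows]
    data = np.zeros((n, n))
    if lengths == [n] * n:
        for i, (_name, vals) in enumerate(rows):
            data[i, :] = vals
    elif lengths == list(range(n)):
        for i, (_name, vals) in enumerate(rows):
            for j, v in enumerate(vals):
                data[i, j] = data[j, i] = v
    elif lengths == list(range(1, n + 1)):
        for i, (_name, vals) in enumerate(rows):
            for j, v in enumerate(vals):
                data[i, j] = data[j, i] = v
    else:
        raise ValueError("matrix is neither square nor a labelled lower triangle")
    return DistanceMatrix(data, ids=labels)
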
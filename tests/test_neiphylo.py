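"""Nei standard distance, distance matrices, neighbor joining and the
text formats around them."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import DistanceMatrix

import skbio.tree

from karyopool.bandmap import ARMS
from karyopool.neiphylo import (
    distance_matrix,
    nei_distance,
    nj_tree,
    read_newick,
    read_phylip_matrix,
    round3,
    write_newick,
    write_phylip_matrix,
)
from karyopool.popstats import AlleleFrequencyTable


def table(code, b=(1.0,), f=(1.0,)):
    freqs = {arm: {f"p'agi{arm}1": 1.0} for arm in ARMS}
    freqs["B"] = {f"p'agiB{i + 1}": p for i, p in enumerate(b)}
    freqs["F"] = {f"p'agiF{i + 1}": p for i, p in enumerate(f)}
    return AlleleFrequencyTable(code, freqs)


class TestNeiDistance:
    def test_identical_tables(self):
        t = table("X", b=(0.3, 0.7))
        r = nei_distance(t, t)
        assert r.identity == pytest.approx(1.0)
        assert r.distance == pytest.approx(0.0)

    def test_symmetry(self):
        x = table("X", b=(0.3, 0.7), f=(0.9, 0.1))
        y = table("Y", b=(0.8, 0.2))
        assert nei_distance(x, y).distance == pytest.approx(
            nei_distance(y, x).distance
        )

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=3),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_distance_nonnegative(self, wa, wb):
        x = table("X", b=tuple(w / sum(wa) for w in wa))
        y = table("Y", b=tuple(w / sum(wb) for w in wb))
        assert nei_distance(x, y).distance >= 0.0

    def test_shared_monomorphic_loci_dilute_distance(self):
        x = table("X", b=(0.3, 0.7))
        y = table("Y", b=(0.8, 0.2))
        d_all = nei_distance(x, y).distance
        d_b_only = nei_distance(x, y, loci=("B",)).distance
        assert d_b_only > d_all  # dropping shared monomorphic arms inflates D

    def test_missing_locus_rejected(self):
        x = table("X")
        y = AlleleFrequencyTable("Y", {"B": {"p'agiB1": 1.0}})
        with pytest.raises(ValueError):
            nei_distance(x, y)
        with pytest.raises(ValueError):
            nei_distance(x, x, loci=())

    def test_identity_clamped_before_log(self):
        # rounded printed frequencies can push raw I a hair above 1
        x = table("X", b=(0.333, 0.667))
        r = nei_distance(x, x)
        assert r.distance == 0.0


class TestDistanceMatrix:
    def test_identical_tables_give_zero(self):
        m = distance_matrix([table("X", b=(0.3, 0.7)), table("Y", b=(0.3, 0.7))])
        assert float(m["X", "Y"]) == pytest.approx(0.0)

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([table("X"), table("X")])

    def test_matrix_is_symmetric(self, fx):
        m = distance_matrix(fx.tables)
        assert np.allclose(m.data, m.data.T)
        assert np.all(np.diag(m.data) == 0)


from tests_support_trees import random_additive_matrix


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        m = DistanceMatrix(
            np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]),
            ids=["a", "b", "c"],
        )
        t = nj_tree(m)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_two_leaves_rejected(self):
        m = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(20260301)
        for _trial in range(15):
            n = int(rng.integers(4, 9))
            m = random_additive_matrix(rng, n)
            t = nj_tree(m)
            tt = t.tip_tip_distances()
            for a, b in itertools.combinations(m.ids, 2):
                assert float(tt[a, b]) == pytest.approx(float(m[a, b]), abs=1e-9)
            # independent implementation agrees on the topology
            assert t.compare_rfd(skbio.tree.nj(m)) == 0.0

    def test_negative_lengths_clamped(self):
        data = np.array(
            [
                [0, 0.1, 0.6, 0.6],
                [0.1, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.05],
                [0.6, 0.6, 0.05, 0],
            ]
        )
        t = nj_tree(DistanceMatrix(data, ids=list("abcd")))
        assert all(
            (node.length or 0.0) >= 0.0 for node in t.traverse(include_self=False)
        )

    def test_printed_matrix_extremes(self, fx):
        """The two range-border populations attach at opposite ends of
        the chain of Siberian populations."""
        tree = nj_tree(fx.printed_distances)
        assert {t.name for t in tree.tips()} == set(fx.printed_distances.ids)

        def edge_path(a, b):
            na, nb = tree.find(a), tree.find(b)
            anc = {id(x) for x in na.ancestors()} | {id(na)}
            steps_b, cur = 0, nb
            while id(cur) not in anc:
                cur = cur.parent
                steps_b += 1
            steps_a, x = 0, na
            while id(x) != id(cur):
                x = x.parent
                steps_a += 1
            return steps_a + steps_b

        tips = [t.name for t in tree.tips()]
        diameter = max(
            edge_path(a, b) for a, b in itertools.combinations(tips, 2)
        )
        assert edge_path("YAR-RY", "KHA-EV") == diameter


class TestFormats:
    def test_newick_round_trip(self):
        m = DistanceMatrix(
            np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]),
            ids=["a", "b", "c"],
        )
        t = nj_tree(m)
        t2 = read_newick(write_newick(t))
        assert {x.name for x in t2.tips()} == {"a", "b", "c"}
        for tip in t.tips():
            assert t2.find(tip.name).length == pytest.approx(tip.length)

    def test_empty_newick_rejected(self):
        with pytest.raises(ValueError):
            read_newick("   ")

    def test_phylip_square_round_trip(self, fx):
        m = distance_matrix(fx.tables)
        m2 = read_phylip_matrix(write_phylip_matrix(m))
        assert list(m2.ids) == list(m.ids)
        assert np.allclose(m2.data, np.round(m.data, 3), atol=5e-4)

    def test_lower_triangle_dialect(self, fx):
        printed = fx.printed_distances
        assert len(printed.ids) == 10
        assert float(printed["YAR-RY", "NSK-BE"]) == pytest.approx(0.106)
        assert float(printed["KHA-EV", "NSK-ST"]) == pytest.approx(0.013)

    def test_garbage_matrix_rejected(self):
        with pytest.raises(ValueError):
            read_phylip_matrix("")
        with pytest.raises(ValueError):
            read_phylip_matrix("a 1 2 3\nb 4\n")

    def test_rounding_is_half_up(self):
        assert round3(0.0005) == 0.001
        assert round3(0.10649) == 0.106
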
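import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netpharm import (GeneSetCollection, SimConfig, bh_adjust, dotplot,
                      enrich, gen_gene_sets, hypergeom_upper, read_gmt)
from netpharm.errors import FormatError, NetpharmError


def enumeration_upper(k, K, n, N):
    """Exact tail by combinatorial enumeration: sum_i>=k C(K,i)C(N-K,n-i)/C(N,n)."""
    total = sum(math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1))
    return total / math.comb(N, n)


class TestHypergeomUpper:
    def test_zero_overlap_is_one(self):
        assert hypergeom_upper(0, 5, 3, 20) == 1.0

    def test_term_equals_background_is_one(self):
        assert hypergeom_upper(3, 10, 3, 10) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # C(3,2)C(7,1) + C(3,3)C(7,0) over C(10,3) = 22/120
        assert hypergeom_upper(2, 3, 3, 10) == pytest.approx(22 / 120)

    def test_invalid_arguments_rejected(self):
        for bad in [(4, 3, 5, 10), (1, 11, 3, 10), (1, 3, 11, 10), (-1, 3, 3, 10)]:
            with pytest.raises(NetpharmError):
                hypergeom_upper(*bad)

    def test_non_increasing_in_k(self):
        vals = [hypergeom_upper(k, 6, 5, 15) for k in range(6)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_exhaustive_small_universe(self):
        """Direct draw-by-draw enumeration over all C(N, n) subsets, N <= 12."""
        N, K, n = 9, 4, 5
        members = set(range(K))
        for k in range(0, min(K, n) + 1):
            count = sum(1 for draw in itertools.combinations(range(N), n)
                        if len(members & set(draw)) >= k)
            assert hypergeom_upper(k, K, n, N) == \
                pytest.approx(count / math.comb(N, n), abs=1e-12)


class TestBhAdjust:
    def test_single_p_is_itself(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stays_equal(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_order_invariance(self, p):
        fwd = bh_adjust(p)
        rev = bh_adjust(p[::-1])
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_dominates_input_and_caps_at_one(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(NetpharmError):
            bh_adjust([0.5, 1.5])


def small_collection():
    return GeneSetCollection(terms={
        "T1": ("term one", "bp", {"A", "B", "C", "D"}),
        "T2": ("term two", "bp", {"C", "D", "E", "F", "G", "H"}),
        "T3": ("term three", "mf", {"H", "I", "J"}),
    })


class TestEnrich:
    def test_disjoint_list_gives_empty_result(self):
        assert enrich({"ZZZ", "YYY"}, small_collection()) == []

    def test_single_covering_term_ranks_first(self):
        coll = GeneSetCollection(
            terms={"HIT": ("hit", "bp", {"A", "B", "C"}),
                   "BIG": ("bg", "bp", {f"X{i}" for i in range(40)} | {"A"})})
        rows = enrich({"A", "B", "C"}, coll, fdr_max=1.0, top_k=None)
        assert rows[0].term_id == "HIT"

    def test_fdr1_topk_none_includes_every_overlapping_term(self):
        rows = enrich({"A", "C", "H"}, small_collection(), fdr_max=1.0, top_k=None)
        assert {r.term_id for r in rows} == {"T1", "T2", "T3"}
        assert all(r.gene_ratio <= 1 for r in rows)

    def test_row_counts_are_consistent(self):
        rows = enrich({"A", "C", "H"}, small_collection(), fdr_max=1.0, top_k=None)
        for r in rows:
            assert 0 <= r.k <= min(r.K, r.n)
            assert r.gene_ratio == pytest.approx(r.k / r.n)
            assert len(r.members) == r.k

    def test_planted_term_ranks_first(self):
        cfg = SimConfig(seed=3, n_terms=200, planted_term_overlap=15)
        rng = np.random.default_rng(17)
        target_list = {f"G{i:05d}" for i in rng.choice(range(1, 5001), 20, replace=False)}
        coll, truth = gen_gene_sets(cfg, target_list, n_planted=1)
        rows = enrich(target_list, coll, fdr_max=1.0, top_k=None)
        assert rows[0].term_id == truth["planted_terms"][0]

    def test_ease_variant_is_more_conservative(self):
        coll = small_collection()
        plain = enrich({"A", "B", "C"}, coll, fdr_max=1.0, top_k=None)
        eased = enrich({"A", "B", "C"}, coll, fdr_max=1.0, top_k=None, ease=True)
        # a term whose EASE p reaches 1.0 falls below the fdr < 1 gate, which
        # is itself a more conservative outcome
        by_id = {r.term_id: r.p for r in eased}
        assert all(by_id.get(r.term_id, 1.0) >= r.p for r in plain)

    def test_deterministic_tie_break(self):
        coll = GeneSetCollection(terms={
            "B_TERM": ("b", "bp", {"A", "X1", "X2"}),
            "A_TERM": ("a", "bp", {"A", "Y1", "Y2"}),
        })
        rows = enrich({"A"}, coll, fdr_max=1.0, top_k=None)
        assert [r.term_id for r in rows] == ["A_TERM", "B_TERM"]


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        from netpharm.enrichment import write_gmt
        coll = small_collection()
        write_gmt(coll, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert back.terms.keys() == coll.terms.keys()
        for tid in coll.terms:
            assert back.terms[tid][2] == coll.terms[tid][2]

    def test_malformed_line_rejected(self):
        with pytest.raises(FormatError):
            read_gmt(io.StringIO("T1\tonly-description\n"))

    def test_empty_term_rejected(self):
        with pytest.raises(FormatError):
            GeneSetCollection(terms={"T": ("x", "bp", set())})


class TestDotplot:
    def test_single_row(self, tmp_path):
        rows = enrich({"A", "B", "C"}, small_collection(), fdr_max=1.0, top_k=1)
        out = tmp_path / "d.png"
        dotplot(rows, out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_rows_rejected(self):
        with pytest.raises(NetpharmError):
            dotplot([])

    def test_shuffled_input_gives_same_ordering(self, tmp_path):
        rows = enrich({"A", "C", "H"}, small_collection(), fdr_max=1.0, top_k=None)
        fig1 = dotplot(rows)
        fig2 = dotplot(rows[::-1])
        labels1 = [t.get_text() for t in fig1.axes[0].get_yticklabels()]
        labels2 = [t.get_text() for t in fig2.axes[0].get_yticklabels()]
        assert labels1 == labels2
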
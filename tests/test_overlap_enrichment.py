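"""Hypergeometric tails, overlap statistics, Venn partitions, enrichment."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from modscreen import datasets
from modscreen.overlap_enrichment import (
    GeneSet,
    _log_hypergeom_pmf,
    annotation_enrichment,
    hypergeom_tail,
    overlap_counts,
    overlap_stats,
    venn_partition,
)


# ---------------------------------------------------------------- tail


def test_tail_at_zero_is_one():
    assert hypergeom_tail(100, 10, 10, 0) == 1.0


def test_tail_exhaustive_enumeration_small_universe():
    """P(X >= x) equals the fraction of all C(N, n) draws with >= x hits,
    enumerated exhaustively for N <= 10."""
    for N in (5, 8, 10):
        universe = range(N)
        for K in range(N + 1):
            good = set(range(K))
            for n in range(N + 1):
                draws = list(itertools.combinations(universe, n))
                for x in range(min(K, n) + 1):
                    frac = sum(len(good & set(d)) >= x for d in draws) / len(draws)
                    assert hypergeom_tail(N, K, n, x) == pytest.approx(frac, rel=1e-10)


@given(
    N=st.integers(1, 5000),
    K=st.integers(0, 5000),
    n=st.integers(0, 5000),
    x=st.integers(0, 5000),
)
def test_tail_matches_scipy_sf(N, K, n, x):
    if not (K <= N and n <= N and x <= min(K, n)):
        return
    expected = stats.hypergeom.sf(x - 1, N, K, n)
    assert hypergeom_tail(N, K, n, x) == pytest.approx(expected, rel=1e-8, abs=1e-300)


@given(N=st.integers(2, 2000), K=st.integers(1, 2000), n=st.integers(1, 2000))
def test_pmf_normalizes(N, K, n):
    if K > N or n > N:
        return
    lo, hi = max(0, n - (N - K)), min(K, n)
    ks = np.arange(lo, hi + 1)
    total = np.exp(_log_hypergeom_pmf(ks, N, K, n)).sum()
    assert total == pytest.approx(1.0, abs=1e-12)


def test_tail_symmetric_in_set_roles():
    for (N, K, n, x) in [(100, 30, 20, 10), (18833, 1354, 596, 146)]:
        assert hypergeom_tail(N, K, n, x) == pytest.approx(
            hypergeom_tail(N, n, K, x), rel=1e-10
        )


def test_tail_extreme_underflow_regime():
    """Stable far below double underflow of individual terms."""
    p = hypergeom_tail(18833, 1354, 596, 250)
    assert 0 < p < 1e-100


def test_tail_validates_counts():
    with pytest.raises(ValueError):
        hypergeom_tail(10, 12, 5, 1)
    with pytest.raises(ValueError):
        hypergeom_tail(10, 4, 5, 5)


# ---------------------------------------------------------------- overlap


def test_overlap_stats_counts_and_fold():
    s1 = GeneSet("a", frozenset("abcd"))
    s2 = GeneSet("b", frozenset("cdef"))
    res = overlap_stats(s1, s2, 10)
    assert res.overlap == 2
    assert res.fold_enrichment == pytest.approx((2 / 4) / (4 / 10))
    assert res.p_hyper == pytest.approx(hypergeom_tail(10, 4, 4, 2), rel=1e-12)


def test_overlap_universe_smaller_than_set_errors():
    s = GeneSet("a", frozenset("abcdef"))
    with pytest.raises(ValueError):
        overlap_stats(s, s, 3)


def test_certain_containment_is_null():
    # set1 covers the whole universe: fold 1, P 1
    s1 = GeneSet("all", frozenset(str(i) for i in range(10)))
    s2 = GeneSet("sub", frozenset("012"))
    res = overlap_stats(s1, s2, 10)
    assert res.fold_enrichment == pytest.approx(1.0)
    assert res.p_hyper == 1.0


def test_published_count_tuples_reproduce_printed_folds_and_percents():
    for fx in datasets.overlap_fixtures():
        res = overlap_counts(fx.N, fx.K, fx.n, fx.x)
        assert round(res.fold_enrichment, 1) == pytest.approx(fx.printed_fold)
        if fx.printed_percent is not None:
            assert round(res.overlap_percent, 1) == pytest.approx(fx.printed_percent)


# ---------------------------------------------------------------- venn


def test_venn_two_sets_with_universe():
    A = GeneSet("A", frozenset("abc"))
    B = GeneSet("B", frozenset("bcd"))
    cells = venn_partition([A, B], universe="abcdef")
    assert sorted(cells[(True, False)]) == ["a"]
    assert sorted(cells[(False, True)]) == ["d"]
    assert sorted(cells[(True, True)]) == ["b", "c"]
    assert sorted(cells[(False, False)]) == ["e", "f"]
    assert sum(len(v) for v in cells.values()) == 6


def test_venn_disjoint_sets_without_universe():
    A = GeneSet("A", frozenset("ab"))
    B = GeneSet("B", frozenset("cd"))
    cells = venn_partition([A, B])
    assert set(cells) == {(True, False), (False, True)}


def test_venn_invariant_to_set_order():
    A = GeneSet("A", frozenset("abc"))
    B = GeneSet("B", frozenset("bcd"))
    C = GeneSet("C", frozenset("ce"))
    c1 = venn_partition([A, B, C], universe="abcdefg")
    c2 = venn_partition([C, A, B], universe="abcdefg")
    remapped = {(sa, sb, sc): ids for (sc, sa, sb), ids in c2.items()}
    assert c1 == remapped


def test_venn_rejects_ids_outside_universe_and_too_many_sets():
    A = GeneSet("A", frozenset("az"))
    with pytest.raises(ValueError):
        venn_partition([A], universe="abc")
    with pytest.raises(ValueError):
        venn_partition([GeneSet(str(i), frozenset("a")) for i in range(6)])


# ---------------------------------------------------------------- enrichment


def _toy_catalog():
    return [
        GeneSet("hit_term", frozenset(f"g{i}" for i in range(10))),       # K=10
        GeneSet("null_term", frozenset(f"h{i}" for i in range(20))),      # K=20
    ]


def test_annotation_enrichment_fold_and_p():
    query = GeneSet("q", frozenset([f"g{i}" for i in range(5)] + ["x1", "x2", "x3", "x4", "x5"]))
    df = annotation_enrichment(query, _toy_catalog(), universe_size=100, fdr=False)
    hit = df.set_index("term").loc["hit_term"]
    assert hit.x == 5
    assert hit.fold == pytest.approx((5 / 10) / (10 / 100))
    assert hit.p == pytest.approx(hypergeom_tail(100, 10, 10, 5), rel=1e-12)
    null = df.set_index("term").loc["null_term"]
    assert null.x == 0 and null.p == 1.0


def test_ease_mode_is_conservative():
    query = GeneSet("q", frozenset(f"g{i}" for i in range(8)))
    hyper = annotation_enrichment(query, _toy_catalog(), 100, mode="hypergeometric")
    ease = annotation_enrichment(query, _toy_catalog(), 100, mode="ease")
    merged = hyper.merge(ease, on="term", suffixes=("_h", "_e"))
    for row in merged.itertuples():
        if row.x_h >= 1:
            assert row.p_e >= row.p_h


def test_empty_query_gives_unit_pvalues():
    df = annotation_enrichment(GeneSet("q", frozenset()), _toy_catalog(), 100)
    assert (df["p"] == 1.0).all()


def test_enrichment_respects_explicit_universe():
    query = GeneSet("q", frozenset(["g0", "g1", "outside"]))
    df = annotation_enrichment(
        query, _toy_catalog(), 0,
        universe=[f"g{i}" for i in range(10)] + [f"h{i}" for i in range(20)],
    )
    assert df.set_index("term").loc["hit_term", "n"] == 2  # 'outside' dropped
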
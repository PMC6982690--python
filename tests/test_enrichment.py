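"""Hypergeometric ORA and Benjamini-Hochberg adjustment."""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_hypergeom_tail
from herbnetscreen.enrichment import bh_adjust, hypergeom_tail, run_ora, top_terms
from herbnetscreen.models import (
    Category,
    EnrichmentResult,
    GeneSet,
    GeneSetCollection,
)


# -------------------------------------------------------- hypergeom_tail


def test_tail_k0_is_one():
    assert hypergeom_tail(0, 4, 5, 10) == 1.0


def test_tail_forced_draw_is_one():
    assert hypergeom_tail(5, 5, 5, 5) == 1.0


def test_tail_worked_example():
    """k=3 of K=4 annotated among n=5 drawn from N=10: 66/252 of all draws."""
    assert hypergeom_tail(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)
    assert oracle_hypergeom_tail(3, 4, 5, 10) == Fraction(66, 252)


def test_tail_invalid_bounds():
    with pytest.raises(ValueError):
        hypergeom_tail(3, 2, 5, 10)
    with pytest.raises(ValueError):
        hypergeom_tail(0, 11, 5, 10)


def test_tail_matches_enumeration_small():
    """Exact agreement with draw enumeration on a spread of small cases."""
    for N in (5, 8, 10):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for k in range(min(K, n) + 1):
                    expected = float(oracle_hypergeom_tail(k, K, n, N))
                    assert hypergeom_tail(k, K, n, N) == pytest.approx(
                        expected, abs=1e-12
                    )


def test_tail_matches_scipy_large():
    from scipy.stats import hypergeom

    rng = random.Random(2)
    for _ in range(50):
        N = rng.randint(20, 2000)
        K = rng.randint(1, N)
        n = rng.randint(1, N)
        k = rng.randint(0, min(K, n))
        expected = float(hypergeom.sf(k - 1, N, K, n))
        assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, rel=1e-9)


def test_tail_non_increasing_in_k():
    for K, n, N in [(4, 5, 10), (7, 9, 20), (3, 3, 6)]:
        vals = [hypergeom_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


# -------------------------------------------------------------- bh_adjust


def test_bh_single_p_unchanged():
    assert bh_adjust([0.03]) == [pytest.approx(0.03)]


def test_bh_all_equal_unchanged():
    assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)


def test_bh_worked_example():
    """Step-up on 0.01..0.04 collapses every q to 0.04."""
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_envelope_idempotent_and_rank_monotone(p):
    """Adjusted values dominate the raw ones, stay in [0,1], are monotone
    along the sorted-p order, and are a fixed point of the isotonic
    (min-accumulate) envelope that defines the step-up."""
    q = bh_adjust(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.asarray(q)[order]
    assert np.all(np.diff(q_sorted) >= -1e-12)
    assert np.all(np.asarray(q) >= np.asarray(p) - 1e-12)
    assert np.all((np.asarray(q) >= 0) & (np.asarray(q) <= 1))
    envelope = np.minimum.accumulate(q_sorted[::-1])[::-1]
    assert envelope == pytest.approx(q_sorted, abs=0)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.random(200)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    assert bh_adjust(p) == pytest.approx(expected.tolist(), abs=1e-12)


# ----------------------------------------------------------------- run_ora


def _collection(seed: int, n_sets: int = 8, universe: int = 30) -> GeneSetCollection:
    rng = random.Random(seed)
    genes = [f"G{i}" for i in range(universe)]
    return GeneSetCollection(
        GeneSet(
            f"S{i}",
            "d",
            rng.choice(list(Category)),
            frozenset(rng.sample(genes, rng.randint(3, 12))),
        )
        for i in range(n_sets)
    )


def test_ora_empty_query():
    coll = _collection(0)
    # k=0 everywhere -> p_raw = 1 for every set -> nothing significant
    for r in run_ora(set(), coll, filter_on="none"):
        assert r.p_raw == 1.0
    assert run_ora(set(), coll) == []


def test_ora_whole_background_set_never_significant():
    genes = frozenset(f"G{i}" for i in range(10))
    coll = GeneSetCollection(
        [GeneSet("all", "d", Category.PATHWAY, genes)]
    )
    (res,) = run_ora({"G0", "G1"}, coll, filter_on="none", max_size=100)
    assert res.p_raw == 1.0


def test_ora_query_outside_background_rejected():
    coll = _collection(1)
    with pytest.raises(ValueError, match="ZZZ"):
        run_ora({"ZZZ"}, coll)


def test_ora_alpha_extremes():
    coll = _collection(2)
    query = set(list(coll.all_members())[:6])
    everything = run_ora(query, coll, alpha=1.000001, filter_on="p_raw", max_size=500)
    eligible = [gs for gs in coll if 3 <= len(gs.members & coll.all_members()) <= 500]
    assert len(everything) == len(eligible)
    assert run_ora(query, coll, alpha=0.0) == []


@pytest.mark.parametrize("seed", range(6))
def test_ora_agrees_with_enumeration(seed):
    """Randomized small instances match the brute-force draw enumeration."""
    rng = random.Random(seed)
    universe = [f"G{i}" for i in range(rng.randint(8, 12))]
    background = set(universe)
    coll = GeneSetCollection(
        GeneSet(
            f"S{i}", "d", Category.PATHWAY,
            frozenset(rng.sample(universe, rng.randint(3, len(universe)))),
        )
        for i in range(4)
    )
    query = set(rng.sample(universe, rng.randint(1, len(universe))))
    results = run_ora(query, coll, background=background, filter_on="none")
    assert len(results) >= 1
    for r in results:
        expected = float(oracle_hypergeom_tail(r.k, r.K, r.n, r.N))
        assert r.p_raw == pytest.approx(expected, abs=1e-12)


def test_ora_sorted_by_p_then_id():
    coll = _collection(3)
    query = set(list(coll.all_members())[:8])
    results = run_ora(query, coll, filter_on="none")
    keys = [(r.p_raw, r.set_id) for r in results]
    assert keys == sorted(keys)


# --------------------------------------------------------------- top_terms


def _fake_results(n_per_cat: dict[Category, int]) -> list:
    out = []
    i = 0
    for cat, n in n_per_cat.items():
        for j in range(n):
            out.append(
                EnrichmentResult(
                    f"{cat.value}_{j:03d}", cat, 1, 3, 5, 50,
                    p_raw=0.001 * (i + 1), p_adj=0.002 * (i + 1),
                    hits=frozenset({"G1"}),
                )
            )
            i += 1
    return out


def test_top_terms_fewer_than_limit_returns_all():
    res = _fake_results({Category.BP: 4})
    assert len(top_terms(res, {Category.BP: 30})) == 4


def test_top_terms_limit_zero_is_empty():
    res = _fake_results({Category.BP: 4})
    assert top_terms(res, {Category.BP: 0}) == []


def test_top_terms_caps_per_category():
    """With 40/35/30 significant terms and limits 30/30/25, 85 survive."""
    res = _fake_results({Category.BP: 40, Category.CC: 35, Category.MF: 30})
    kept = top_terms(res, {"BP": 30, "CC": 30, "MF": 25})
    assert len(kept) == 85
    by_cat = {c: sum(1 for r in kept if r.category == c) for c in Category}
    assert by_cat[Category.BP] == 30
    assert by_cat[Category.CC] == 30
    assert by_cat[Category.MF] == 25
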
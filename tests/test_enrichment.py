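"""Hypergeometric/EASE oracles, clustering arithmetic, running-sum engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isopipe.enrichment import (
    cluster_annotations,
    cluster_es,
    cohen_kappa,
    ease_p,
    enrich_list,
    gsea_score,
    gsea_significance,
    hypergeom_upper,
)
from isopipe.errors import ConfigurationError, UsageError, ValidationError
from isopipe.models import GeneSetCollection


def hyper_tail_oracle(k, K, n, N):
    """Exact upper-tail by integer-arithmetic pmf summation."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def gsea_oracle(ranked, gene_set, p=1.0):
    """Literal step-by-step running sum, max |deviation| with sign."""
    hits = [g in set(gene_set) for g, _ in ranked]
    nr = sum(abs(s) ** p for (g, s), h in zip(ranked, hits) if h)
    H, L = sum(hits), len(ranked)
    run, best = 0.0, 0.0
    for (g, s), h in zip(ranked, hits):
        if h:
            run += (abs(s) ** p / nr) if nr > 0 else 1.0 / H
        else:
            run -= 1.0 / (L - H)
        if abs(run) > abs(best):
            best = run
    return best


# ---------------------------------------------------------------------------
# hypergeometric + EASE

def test_tail_bounds():
    assert hypergeom_upper(0, 5, 4, 10) == 1.0
    with pytest.raises(ValidationError):
        hypergeom_upper(5, 4, 10, 10)


def test_tail_worked_instance():
    # all 4 draws marked: C(5,4)*C(5,0)/C(10,4)
    expect = math.comb(5, 4) / math.comb(10, 4)
    assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(expect)


def test_tail_monotone_in_k():
    ps = [hypergeom_upper(k, 8, 6, 20) for k in range(0, 7)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_ease_is_jackknifed_tail():
    assert ease_p(1, 8, 6, 20) == 1.0
    assert ease_p(5, 8, 6, 20) == pytest.approx(hyper_tail_oracle(4, 8, 6, 20))


@settings(max_examples=80, deadline=None)
@given(st.integers(1, 25), st.data())
def test_tail_and_ease_match_exact_oracle(N, data):
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    k = data.draw(st.integers(0, min(K, n)))
    assert hypergeom_upper(k, K, n, N) == pytest.approx(
        hyper_tail_oracle(k, K, n, N), rel=1e-10
    )
    ek = ease_p(k, K, n, N)
    assert ek == pytest.approx(
        1.0 if k <= 1 else hyper_tail_oracle(k - 1, K, n, N), rel=1e-10
    )
    assert ek >= hypergeom_upper(k, K, n, N) - 1e-12


# ---------------------------------------------------------------------------
# list enrichment

UNIVERSE = [f"g{i}" for i in range(40)]


def _collection():
    return GeneSetCollection(
        {
            "S1": ("one", tuple(UNIVERSE[:10])),
            "S2": ("two", tuple(UNIVERSE[5:20])),
            "S3": ("three", tuple(UNIVERSE[30:])),
        }
    )


def test_full_category_has_maximal_overlap():
    records = enrich_list(UNIVERSE[:10], _collection(), UNIVERSE)
    rec = {r.category_id: r for r in records}
    assert rec["S1"].k == rec["S1"].K == 10


def test_disjoint_list_yields_nothing():
    records = enrich_list(UNIVERSE[20:30], _collection(), UNIVERSE)
    assert records == []


def test_empty_universe_rejected():
    with pytest.raises(ConfigurationError):
        enrich_list(["a"], _collection(), [])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_counts_match_bruteforce_intersections(seed):
    rng = np.random.default_rng(seed)
    lst = list(rng.choice(UNIVERSE, size=12, replace=False))
    records = enrich_list(lst, _collection(), UNIVERSE)
    coll = _collection()
    for r in records:
        members = set(coll.members(r.category_id)) & set(UNIVERSE)
        assert r.k == len(members & set(lst))
        assert r.K == len(members)
        assert r.n == len(set(lst)) and r.N == 40
        assert r.p_hyper == pytest.approx(
            hyper_tail_oracle(r.k, r.K, r.n, r.N)
        )


# ---------------------------------------------------------------------------
# clustering

def test_kappa_identical_and_disjoint():
    x = np.array([1, 1, 0, 0], bool)
    assert cohen_kappa(x, x) == 1.0
    y = np.array([0, 0, 1, 1], bool)
    assert cohen_kappa(x, y) == -1.0


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(6)
    for _ in range(10):
        x = rng.random(50) < 0.3
        y = rng.random(50) < 0.4
        if len(set(x)) < 2 and len(set(y)) < 2:
            continue
        assert cohen_kappa(x, y) == pytest.approx(
            cohen_kappa_score(x, y), abs=1e-12
        )


def test_cluster_es_closed_forms():
    assert cluster_es([0.01, 0.0001]) == pytest.approx(3.0)
    assert cluster_es([0.01, 0.01, 0.01]) == pytest.approx(2.0)
    assert cluster_es([0.001]) == pytest.approx(3.0)  # singleton


def test_identical_categories_cluster_together():
    coll = GeneSetCollection(
        {
            "A": ("a", tuple(UNIVERSE[:10])),
            "B": ("b", tuple(UNIVERSE[:10])),
            "C": ("c", tuple(UNIVERSE[25:])),
        }
    )
    records = enrich_list(UNIVERSE[:12], coll, UNIVERSE)
    clusters = cluster_annotations(records, coll, UNIVERSE)
    grouped = [set(c.members) for c in clusters]
    assert {"A", "B"} in grouped


def test_es_boundary_not_significant_at_two():
    class Rec:
        def __init__(self, cid, p):
            self.category_id = cid
            self.p_ease = p

    coll = GeneSetCollection({"A": ("a", tuple(UNIVERSE[:5]))})
    clusters = cluster_annotations(
        [Rec("A", 0.01)], coll, UNIVERSE
    )
    (c,) = clusters
    assert c.es == pytest.approx(2.0)
    assert not c.significant  # strict '>' at the threshold


def test_cluster_es_member_order_invariant():
    assert cluster_es([0.01, 0.0001]) == cluster_es([0.0001, 0.01])


# ---------------------------------------------------------------------------
# running-sum engine

def test_es_whole_list_is_one():
    ranked = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
    assert gsea_score(ranked, ["a", "b", "c"]) == pytest.approx(1.0)


def test_es_hand_worked_running_sum():
    ranked = [("g1", 3.0), ("g2", 2.0), ("g3", 1.0), ("g4", -1.0)]
    assert gsea_score(ranked, ["g1", "g3"]) == pytest.approx(0.75)


def test_es_sign_reversal_antisymmetry():
    ranked = [("a", 3.0), ("b", 1.0), ("c", -0.5), ("d", -2.0)]
    flipped = [(g, -s) for g, s in reversed(ranked)]
    assert gsea_score(flipped, ["a", "b"]) == pytest.approx(
        -gsea_score(ranked, ["a", "b"])
    )


def test_es_empty_intersection_rejected():
    with pytest.raises(UsageError):
        gsea_score([("a", 1.0)], ["zzz"])


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_es_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 21))
    scores = np.sort(rng.normal(size=L))[::-1]
    ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
    size = int(rng.integers(1, L + 1))
    gene_set = [f"g{i}" for i in rng.choice(L, size=size, replace=False)]
    p = float(rng.choice([0.0, 1.0, 2.0]))
    assert gsea_score(ranked, gene_set, p) == pytest.approx(
        gsea_oracle(ranked, gene_set, p)
    )


def test_significance_detects_top_loaded_set():
    rng = np.random.default_rng(7)
    scores = np.sort(rng.normal(0, 1, 60))[::-1] + np.linspace(2, -2, 60)
    ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
    coll = GeneSetCollection(
        {"TOP": ("top genes", tuple(f"g{i}" for i in range(8)))}
    )
    (rec,) = gsea_significance(ranked, coll, n_perm=500, seed=1)
    assert rec.es > 0
    assert rec.p < 0.05


def test_significance_deterministic_given_seed():
    ranked = [(f"g{i}", float(10 - i)) for i in range(20)]
    coll = GeneSetCollection(
        {"A": ("a", ("g1", "g5", "g9")), "B": ("b", ("g2", "g12", "g19"))}
    )
    r1 = gsea_significance(ranked, coll, n_perm=200, seed=42)
    r2 = gsea_significance(ranked, coll, n_perm=200, seed=42)
    assert [(r.set_id, r.es, r.p, r.q) for r in r1] == [
        (r.set_id, r.es, r.p, r.q) for r in r2
    ]
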
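"""Normalization, filtering, testing, BH adjustment and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopipe.diffexpr import test_two_group as welch_two_group
from isopipe.diffexpr import (
    adjust_bh,
    between_group_recenter,
    filter_low_expression,
    overlap_and_unique,
    summarize_contrast,
    tmm_polish,
    upper_quartile_normalize,
)
from isopipe.errors import (
    DesignError,
    NormalizationError,
    UsageError,
    ValidationError,
)
from isopipe.models import DEResult

from conftest import make_matrix


def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# upper-quartile normalization

def test_uq_identical_samples_unchanged():
    vals = np.tile([[4.0], [8.0], [0.0], [16.0]], (1, 4))
    mat = make_matrix(vals, 2, 2)
    norm, factors = upper_quartile_normalize(mat)
    assert np.allclose(factors, 1.0)
    pd.testing.assert_frame_equal(norm.values, mat.values)


def test_uq_doubled_sample_gets_double_factor():
    base = np.array([3.0, 6.0, 0.0, 12.0, 24.0])
    vals = np.column_stack([base, 2 * base, base, 2 * base])
    mat = make_matrix(vals, 2, 2)
    norm, factors = upper_quartile_normalize(mat)
    f = factors.to_numpy()
    assert f[1] == pytest.approx(2 * f[0])
    # normalized columns coincide
    arr = norm.values.to_numpy()
    assert np.allclose(arr[:, 0], arr[:, 1])
    assert np.allclose(arr[:, 0], arr[:, 3])


def test_uq_row_order_invariance():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 100, size=(20, 4)).astype(float)
    mat = make_matrix(vals, 2, 2)
    perm = rng.permutation(20)
    mat_perm = make_matrix(vals[perm], 2, 2)
    _, f1 = upper_quartile_normalize(mat)
    _, f2 = upper_quartile_normalize(mat_perm)
    assert np.allclose(f1.to_numpy(), f2.to_numpy())


def test_uq_all_zero_sample_rejected():
    vals = np.array([[1.0, 0.0, 2.0, 3.0], [4.0, 0.0, 5.0, 6.0]])
    mat = make_matrix(vals, 2, 2)
    with pytest.raises(NormalizationError, match="c1"):
        upper_quartile_normalize(mat)


def test_tmm_polish_identity_on_balanced_data():
    rng = np.random.default_rng(1)
    vals = rng.poisson(100, size=(100, 6)).astype(float)
    mat = make_matrix(vals, 3, 3)
    polished, factors = tmm_polish(mat)
    assert np.allclose(factors.to_numpy(), 1.0, atol=0.05)


def test_recenter_removes_global_offset():
    rng = np.random.default_rng(2)
    vals = rng.poisson(200, size=(60, 8)).astype(float)
    vals[:, 4:] *= 2.0  # group B globally doubled
    mat = make_matrix(vals, 4, 4)
    ga, gb = mat.samples[:4], mat.samples[4:]
    fixed, offset = between_group_recenter(mat, ga, gb)
    assert offset == pytest.approx(1.0, abs=0.1)
    res = welch_two_group(fixed, ga, gb, contrast="c")
    lfc = np.array([r.log2fc for r in res])
    assert abs(np.median(lfc)) < 0.05


# ---------------------------------------------------------------------------
# low-expression filter

def test_filter_boundary_at_threshold():
    vals = np.array(
        [[2.0, 2.0, 2.0, 3.0],   # gene gA total 9 -> dropped
         [2.0, 2.0, 3.0, 3.0]]   # gene gB total 10 -> kept
    )
    mat = make_matrix(vals, 2, 2, genes=["gA", "gB"])
    kept = filter_low_expression(mat, min_reads=10)
    assert kept.unit_ids == ["t1"]


def test_filter_zero_threshold_is_identity():
    vals = np.zeros((3, 4))
    mat = make_matrix(vals, 2, 2)
    kept = filter_low_expression(mat, min_reads=0)
    assert kept.unit_ids == mat.unit_ids


def test_filter_drops_whole_gene_with_isoforms():
    # gene g0 has two isoforms totalling 8 -> both dropped together
    vals = np.array([[1.0] * 4, [1.0] * 4, [10.0] * 4])
    mat = make_matrix(vals, 2, 2, genes=["g0", "g0", "g1"])
    kept = filter_low_expression(mat, min_reads=10)
    assert kept.unit_ids == ["t2"]


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_filter_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 30))
    vals = rng.integers(0, 8, size=(n, 4)).astype(float)
    genes = [f"g{int(rng.integers(0, 6))}" for _ in range(n)]
    mat = make_matrix(vals, 2, 2, genes=genes)
    kept = filter_low_expression(mat, min_reads=10)
    # oracle: independent row summation per gene
    totals = {}
    for i, g in enumerate(genes):
        totals[g] = totals.get(g, 0) + vals[i].sum()
    expect = [f"t{i}" for i, g in enumerate(genes) if totals[g] >= 10]
    assert kept.unit_ids == expect


# ---------------------------------------------------------------------------
# two-group test

def test_identical_groups_null_result():
    vals = np.tile([[10.0], [50.0]], (1, 4))
    mat = make_matrix(vals, 2, 2)
    res = welch_two_group(mat, ["c0", "c1"], ["b0", "b1"], contrast="c")
    for r in res:
        assert r.log2fc == 0.0
        assert r.p == 1.0
        assert r.status == "non"


def test_label_swap_antisymmetry():
    rng = np.random.default_rng(3)
    vals = rng.poisson(50, size=(30, 8)).astype(float)
    mat = make_matrix(vals, 4, 4)
    ga, gb = mat.samples[:4], mat.samples[4:]
    fwd = welch_two_group(mat, ga, gb, contrast="c")
    rev = welch_two_group(mat, gb, ga, contrast="c")
    for f, r in zip(fwd, rev):
        assert f.log2fc == pytest.approx(-r.log2fc)
        assert f.p == pytest.approx(r.p)


def test_sample_column_order_invariance():
    rng = np.random.default_rng(4)
    vals = rng.poisson(50, size=(20, 8)).astype(float)
    mat = make_matrix(vals, 4, 4)
    ga, gb = mat.samples[:4], mat.samples[4:]
    shuffled = mat.select_samples(list(rng.permutation(mat.samples)))
    a = welch_two_group(mat, ga, gb, contrast="c")
    b = welch_two_group(shuffled, ga, gb, contrast="c")
    for x, y in zip(a, b):
        assert x.p == pytest.approx(y.p)
        assert x.log2fc == pytest.approx(y.log2fc)


def test_too_few_samples_rejected():
    vals = np.ones((2, 3))
    mat = make_matrix(vals, 1, 2)
    with pytest.raises(DesignError):
        welch_two_group(mat, ["c0"], ["b0", "b1"])


def test_gene_level_uses_isoform_sums():
    vals = np.array([[10.0] * 4, [30.0] * 4])
    mat = make_matrix(vals, 2, 2, genes=["gX", "gX"])
    res = welch_two_group(mat, ["c0", "c1"], ["b0", "b1"], level="gene")
    assert len(res) == 1
    assert res[0].unit_id == "gX"
    assert res[0].mean_a == pytest.approx(40.0)


def test_separate_bh_families_guard():
    """Gene- and isoform-level q-values come from separate BH families:
    pooling the p-values changes the adjusted values."""
    rng = np.random.default_rng(5)
    vals = rng.poisson(40, size=(40, 8)).astype(float)
    vals[:5, 4:] *= 4
    genes = [f"g{i // 2}" for i in range(40)]
    mat = make_matrix(vals, 4, 4, genes=genes)
    ga, gb = mat.samples[:4], mat.samples[4:]
    iso = welch_two_group(mat, ga, gb, level="isoform", contrast="c")
    gene = welch_two_group(mat, ga, gb, level="gene", contrast="c")
    q_iso = np.array([r.q for r in iso])
    pooled = adjust_bh([r.p for r in iso] + [r.p for r in gene])
    assert not np.allclose(q_iso, pooled[: len(iso)])


# ---------------------------------------------------------------------------
# BH adjustment

def test_bh_stepup_worked_example():
    assert np.allclose(
        adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p():
    assert adjust_bh([0.42]) == pytest.approx([0.42])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_hand_stepup(ps):
    q = adjust_bh(ps)
    assert np.allclose(q, bh_oracle(np.array(ps)))
    # order statistics of q are monotone in p
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        adjust_bh([0.5, 1.5])


# ---------------------------------------------------------------------------
# summaries, overlaps

def _mk_results(n_over, n_under, n_non, level="gene", contrast="c"):
    out = []
    for i, status in enumerate(
        ["over"] * n_over + ["under"] * n_under + ["non"] * n_non
    ):
        lfc = 1.0 if status == "over" else (-1.0 if status == "under" else 0.0)
        q = 0.01 if status != "non" else 0.8
        out.append(
            DEResult(f"u{i}", f"g{i}", level, contrast, 1, 1, lfc, q, q, status)
        )
    return out


def test_summary_reproduces_over_expression_predominance():
    s = summarize_contrast(_mk_results(518, 44, 1000))
    assert s.n_de == 562
    assert s.pct_over == 92


def test_summary_no_de_units():
    s = summarize_contrast(_mk_results(0, 0, 10))
    assert s.n_de == 0 and s.pct_over is None


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_summary_matches_bruteforce_tally(seed):
    rng = np.random.default_rng(seed)
    statuses = rng.choice(["over", "under", "non"], size=30)
    results = [
        DEResult(f"u{i}", f"g{i}", "gene", "c", 1, 1,
                 {"over": 1.0, "under": -1.0, "non": 0.0}[s],
                 0.01 if s != "non" else 0.9,
                 0.01 if s != "non" else 0.9, s)
        for i, s in enumerate(statuses)
    ]
    s = summarize_contrast(results)
    assert s.n_over == list(statuses).count("over")
    assert s.n_under == list(statuses).count("under")
    assert s.n_analyzed == 30


def test_summary_mixed_contrasts_rejected():
    results = _mk_results(1, 0, 1) + _mk_results(1, 0, 1, contrast="other")
    with pytest.raises(UsageError):
        summarize_contrast(results)


def test_overlap_set_algebra():
    overlaps, unique = overlap_and_unique(
        {"c1": {"a", "b", "c"}, "c2": {"b", "c", "d"}},
        {"microglia": {"x", "y", "z"}, "macrophage": {"y"}},
    )
    assert overlaps[("c1", "c2")] == 2
    assert unique["microglia"] == {"x", "z"}
    assert unique["macrophage"] == set()


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_overlap_bruteforce_and_bound(seed):
    rng = np.random.default_rng(seed)
    pool = [f"g{i}" for i in range(20)]
    a = set(rng.choice(pool, size=int(rng.integers(0, 15)), replace=False))
    b = set(rng.choice(pool, size=int(rng.integers(0, 15)), replace=False))
    overlaps, _ = overlap_and_unique({"A": a, "B": b})
    assert overlaps[("A", "B")] == len(a & b)
    assert overlaps[("A", "B")] <= min(len(a), len(b))
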
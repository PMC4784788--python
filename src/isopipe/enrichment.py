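"""Over-representation, EASE-style jackknifed enrichment, annotation
clustering, and a weighted running-sum (GSEA-type) enrichment engine.

The EASE p-value is the upper-tail hypergeometric probability after removing
one gene from the overlap, a jackknife that penalises categories supported
by a single gene. Annotation clusters group categories whose gene
memberships agree (Cohen's kappa over membership indicator vectors on the
universe) and score the cluster as minus log10 of the geometric mean of
member EASE p-values; clusters scoring above 2 are deemed significant.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, UsageError, ValidationError
from .models import AnnotationCluster, EnrichmentRecord, GeneSetCollection, GseaRecord

DEFAULT_KAPPA = 0.5
DEFAULT_ES_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# hypergeometric machinery

def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and k <= n <= N and 0 <= K <= N):
        raise ValidationError(
            f"inadmissible hypergeometric instance k={k}, K={K}, n={n}, N={N}"
        )


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    _check_bounds(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE (jackknifed Fisher) p: one gene removed from the overlap."""
    _check_bounds(k, K, n, N)
    if k <= 1:
        return 1.0
    return hypergeom_upper(k - 1, K, n, N)


def enrich_list(
    gene_list: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentRecord]:
    """Score every category against a gene list over a background universe.

    Gene list and categories are intersected with the universe first; only
    categories overlapping the list (k >= 1) are reported, with BH q over
    the tested family. Records come back sorted by p_hyper ascending.
    """
    from .diffexpr import adjust_bh

    uni = set(universe)
    if not uni:
        raise ConfigurationError("empty universe")
    lst = set(gene_list) & uni
    N, n = len(uni), len(lst)
    records = []
    for set_id, (name, members) in collection.sets.items():
        cat = set(members) & uni
        hit = sorted(cat & lst)
        k, K = len(hit), len(cat)
        if k == 0:
            continue
        records.append(
            EnrichmentRecord(
                category_id=set_id,
                name=name,
                k=k, K=K, n=n, N=N,
                p_hyper=hypergeom_upper(k, K, n, N),
                p_ease=ease_p(k, K, n, N),
                overlap_genes=tuple(hit),
            )
        )
    records.sort(key=lambda r: (r.p_hyper, r.category_id))
    qs = adjust_bh([r.p_hyper for r in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
    return records


# ---------------------------------------------------------------------------
# annotation clustering

def cohen_kappa(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa between two binary indicator vectors."""
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    n = x.size
    if n == 0 or x.size != y.size:
        raise UsageError("indicator vectors must be non-empty, equal length")
    po = np.mean(x == y)
    px, py = x.mean(), y.mean()
    pe = px * py + (1 - px) * (1 - py)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def cluster_es(p_ease_values: Sequence[float]) -> float:
    """Enrichment Score: -log10 geometric mean of member EASE p-values."""
    logs = [-math.log10(p) for p in p_ease_values]
    return float(np.mean(logs))


def cluster_annotations(
    records: Sequence[EnrichmentRecord],
    collection: GeneSetCollection,
    universe: Sequence[str],
    kappa_threshold: float = DEFAULT_KAPPA,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
) -> list[AnnotationCluster]:
    """Greedy kappa agglomeration of enriched categories.

    Seeds with the most significant unclustered category and absorbs any
    unclustered category whose membership kappa with *some* cluster member
    reaches the threshold, repeating until stable; singletons are allowed.
    Clusters come back sorted by Enrichment Score descending.
    """
    uni = sorted(set(universe))
    idx = {g: i for i, g in enumerate(uni)}
    vecs = {}
    for rec in records:
        v = np.zeros(len(uni), dtype=bool)
        for g in collection.members(rec.category_id):
            if g in idx:
                v[idx[g]] = True
        vecs[rec.category_id] = v

    by_p = {r.category_id: r.p_ease for r in records}
    remaining = [r.category_id for r in sorted(records, key=lambda r: (r.p_ease, r.category_id))]
    clusters = []
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        grew = True
        while grew:
            grew = False
            for cand in list(remaining):
                if any(
                    cohen_kappa(vecs[cand], vecs[m]) >= kappa_threshold
                    for m in members
                ):
                    members.append(cand)
                    remaining.remove(cand)
                    grew = True
        es = cluster_es([by_p[m] for m in members])
        clusters.append(
            AnnotationCluster(
                members=tuple(members), es=es, significant=es > es_threshold
            )
        )
    clusters.sort(key=lambda c: -c.es)
    return clusters


# ---------------------------------------------------------------------------
# GSEA running sum

def gsea_score(
    ranked: Sequence[tuple[str, float]],
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed maximum deviation of the weighted running sum.

    Hits add |score|^p normalized by the sum of |score|^p over hits; misses
    subtract 1/(L - H). The ranked list must be sorted by score descending
    and contain no duplicate genes.
    """
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise UsageError("duplicate genes in ranked list")
    scores = np.array([s for _, s in ranked], dtype=float)
    in_set = np.array([g in set(gene_set) for g in genes])
    H = int(in_set.sum())
    L = len(genes)
    if H == 0:
        raise UsageError("gene set does not intersect the ranked list")
    w = np.abs(scores) ** weight_exponent
    nr = w[in_set].sum()
    steps = np.empty(L)
    if nr > 0:
        steps[in_set] = w[in_set] / nr
    else:  # all hit scores are zero: fall back to equal hit weights
        steps[in_set] = 1.0 / H
    if L > H:
        steps[~in_set] = -1.0 / (L - H)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_significance(
    ranked: Sequence[tuple[str, float]],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 2,
) -> list[GseaRecord]:
    """Permutation significance of running-sum scores, gene-set permutation.

    For each set the null is built from ``n_perm`` random same-size gene
    draws from the ranked list; p is the smoothed fraction of same-signed
    null scores at least as extreme as the observed one, NES divides by the
    mean |null| of that sign, and q is BH over the tested sets.
    """
    import logging

    from .diffexpr import adjust_bh

    if n_perm < 100:
        logging.getLogger(__name__).warning(
            "n_perm=%d is low; permutation p-values will be coarse", n_perm
        )
    rng = np.random.default_rng(seed)
    genes = [g for g, _ in ranked]
    records = []
    for set_id, (name, members) in sorted(collection.sets.items()):
        hits = set(members) & set(genes)
        if len(hits) < min_size:
            continue
        obs = gsea_score(ranked, hits, weight_exponent)
        size = len(hits)
        null = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(genes, size=size, replace=False)
            null[i] = gsea_score(ranked, draw, weight_exponent)
        same = null[np.sign(null) == np.sign(obs)] if obs != 0 else null
        if same.size:
            p = (np.sum(np.abs(same) >= abs(obs)) + 1) / (same.size + 1)
            nes = obs / np.mean(np.abs(same))
        else:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        records.append(
            GseaRecord(
                set_id=set_id, es=obs, nes=float(nes), p=float(p),
                q=float("nan"), n_hits=size, weight_exponent=weight_exponent,
            )
        )
    qs = adjust_bh([r.p for r in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
    return records
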
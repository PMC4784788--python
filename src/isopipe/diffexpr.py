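"""Two-group differential expression at isoform and gene level.

The engine normalizes libraries by the upper-quartile method, removes genes
with fewer than ``min_reads`` raw reads summed over the contrast's samples,
tests each unit with Welch's unequal-variance t on log2(normalized + c), and
adjusts the resulting p-value family with Benjamini-Hochberg. A unit is
"over" when q < alpha and log2fc > 0, "under" when q < alpha and
log2fc < 0, "non" otherwise; fold changes are B relative to A.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, NormalizationError, UsageError, ValidationError
from .models import ContrastSummary, DEResult, ExpressionMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_READS = 10
DEFAULT_PSEUDOCOUNT = 1.0


def upper_quartile_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale each library by its upper quartile of nonzero counts.

    The per-sample factor is that sample's 75th percentile of nonzero counts
    divided by the geometric mean of those percentiles across samples, so
    factors average to one on the log scale and the normalized matrix keeps
    the original count magnitude.
    """
    uq = {}
    for s in matrix.samples:
        col = matrix.values[s].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise NormalizationError(f"sample {s} has all-zero counts")
        uq[s] = float(np.percentile(nonzero, 75))
    uq = pd.Series(uq)
    factors = uq / np.exp(np.log(uq).mean())
    normalized = matrix.values.div(factors, axis=1)
    return (
        ExpressionMatrix(normalized, matrix.unit_to_gene, matrix.design),
        factors,
    )


def tmm_polish(
    matrix: ExpressionMatrix, trim: float = 0.3, min_units: int = 20
) -> tuple[ExpressionMatrix, pd.Series]:
    """Residual composition correction after upper-quartile scaling.

    Quantile scaling under-corrects when differential expression is
    one-sided: the shifted units drag the quantile with them and every
    null unit inherits a spurious fold change. The polish estimates a
    per-sample residual factor as the trimmed mean of the sample's
    log-ratios to the across-sample geometric mean reference (a
    trimmed-mean-of-M-values in the edgeR tradition), computed over units
    positive in every sample; trimming removes the genuinely changed units
    so the factor tracks the unchanged bulk. Returns factors centered to
    geometric mean one; skipped (factors = 1) when fewer than ``min_units``
    all-positive units are available.
    """
    vals = matrix.values
    positive = vals[(vals > 0).all(axis=1)]
    if len(positive) < min_units:
        factors = pd.Series(1.0, index=vals.columns)
        return matrix, factors
    logx = np.log(positive.to_numpy())
    ref = logx.mean(axis=1, keepdims=True)
    m = logx - ref
    trimmed = stats.trim_mean(m, trim, axis=0)
    factors = pd.Series(np.exp(trimmed - trimmed.mean()), index=vals.columns)
    corrected = vals.div(factors, axis=1)
    return (
        ExpressionMatrix(corrected, matrix.unit_to_gene, matrix.design),
        factors,
    )


def between_group_recenter(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[ExpressionMatrix, float]:
    """Zero the median between-group log2 ratio before testing.

    Under the most-genes-unchanged assumption the median of the per-unit
    mean log2 differences between the groups estimates any composition
    offset the sample-level factors could not remove (genuinely changed
    units sit many standard errors away from the null bulk, so the median
    ignores them). Group B's samples are divided by 2^offset; the offset
    is returned in log2 units.
    """
    la = np.log2(matrix.values[list(group_a)].to_numpy() + pseudocount)
    lb = np.log2(matrix.values[list(group_b)].to_numpy() + pseudocount)
    offset = float(np.median(lb.mean(axis=1) - la.mean(axis=1)))
    corrected = matrix.values.copy()
    corrected[list(group_b)] = corrected[list(group_b)] / (2.0 ** offset)
    return (
        ExpressionMatrix(corrected, matrix.unit_to_gene, matrix.design),
        offset,
    )


def filter_low_expression(
    matrix: ExpressionMatrix, min_reads: int = DEFAULT_MIN_READS
) -> ExpressionMatrix:
    """Drop genes (with all their isoforms) whose raw counts sum below
    ``min_reads`` across the matrix's samples.

    Apply to the contrast-subset matrix *before* normalization so the
    at-least-N-reads rule refers to mapped read counts.
    """
    gene_totals = matrix.values.sum(axis=1).groupby(matrix.unit_to_gene).sum()
    keep_genes = set(gene_totals.index[gene_totals >= min_reads])
    keep = matrix.unit_to_gene.isin(keep_genes)
    return ExpressionMatrix(
        matrix.values[keep].copy(),
        matrix.unit_to_gene[keep].copy(),
        matrix.design,
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_two_group(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    level: str = "isoform",
    contrast: str = "B vs A",
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEResult]:
    """Welch-test every unit of a normalized matrix between two sample groups.

    ``level="gene"`` aggregates isoform abundances to gene sums first.
    log2fc = log2((mean_B + c) / (mean_A + c)); p from Welch's t on
    log2(normalized + c) per sample; q BH-adjusted over this contrast/level
    family.
    """
    if level not in ("gene", "isoform"):
        raise UsageError(f"level must be 'gene' or 'isoform', got {level!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DesignError("each contrast side needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise DesignError(f"samples on both sides: {sorted(overlap)}")

    if level == "gene":
        table = matrix.gene_sums()
        genes = pd.Series(table.index, index=table.index)
    else:
        table = matrix.values
        genes = matrix.unit_to_gene

    a = table[list(group_a)].to_numpy(dtype=float)
    b = table[list(group_b)].to_numpy(dtype=float)
    c = pseudocount
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_b + c) - np.log2(mean_a + c)

    la, lb = np.log2(a + c), np.log2(b + c)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(lb, la, axis=1, equal_var=False).pvalue
    # zero variance on both sides: p undefined by Welch; equal means -> 1,
    # any difference is then deterministic -> 0
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    p = np.where(degenerate & np.isclose(la.mean(axis=1), lb.mean(axis=1)), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    q = adjust_bh(p)

    results = []
    for i, unit in enumerate(table.index):
        if q[i] < alpha:
            status = "over" if log2fc[i] > 0 else ("under" if log2fc[i] < 0 else "non")
        else:
            status = "non"
        results.append(
            DEResult(
                unit_id=str(unit),
                gene_id=str(genes.loc[unit]),
                level=level,
                contrast=contrast,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=float(log2fc[i]),
                p=float(p[i]),
                q=float(q[i]),
                status=status,
            )
        )
    return results


def summarize_contrast(
    results: Iterable[DEResult], alpha: float = DEFAULT_ALPHA
) -> ContrastSummary:
    """Tally DE directions for one contrast/level family.

    ``pct_over`` is reported rounded to the nearest integer (e.g. 518 over
    of 562 DE genes -> 92) and omitted when nothing is differentially
    expressed.
    """
    results = list(results)
    if not results:
        raise UsageError("no results to summarize")
    contrasts = {r.contrast for r in results}
    levels = {r.level for r in results}
    if len(contrasts) > 1 or len(levels) > 1:
        raise UsageError(
            f"mixed families: contrasts {contrasts}, levels {levels}"
        )
    n_over = sum(r.status == "over" for r in results)
    n_under = sum(r.status == "under" for r in results)
    n_de = n_over + n_under
    pct = int(round(100.0 * n_over / n_de)) if n_de else None
    return ContrastSummary(
        contrast=contrasts.pop(),
        level=levels.pop(),
        n_analyzed=len(results),
        n_de=n_de,
        n_over=n_over,
        n_under=n_under,
        pct_over=pct,
    )


def overlap_and_unique(
    de_sets: Mapping[str, set],
    detected_by_cell: Mapping[str, set] | None = None,
) -> tuple[dict[tuple[str, str], int], dict[str, set]]:
    """Pairwise DE overlaps and per-cell uniquely-detected genes.

    Overlaps are |A intersect B| for every pair of named DE sets; unique-to-cell
    lists hold units passing detection in one cell type but not the other,
    computed over the given detection sets (typically within one challenge
    group).
    """
    keys = list(de_sets)
    overlaps = {
        (a, b): len(de_sets[a] & de_sets[b])
        for i, a in enumerate(keys)
        for b in keys[i + 1:]
    }
    unique: dict[str, set] = {}
    if detected_by_cell:
        for cell, detected in detected_by_cell.items():
            others = set().union(
                *(v for k, v in detected_by_cell.items() if k != cell)
            ) if len(detected_by_cell) > 1 else set()
            unique[cell] = set(detected) - others
    return overlaps, unique
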
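"""Synthetic transcriptome and count simulation with planted ground truth.

The generator emulates the study design it is meant to exercise: a
2-challenge (BCG vs Control) x 2-cell-type (microglia vs macrophage) layout
with 12 replicates per cell, negative-binomial counts, a differential
expression signal dominated by over-expression, and genes whose isoforms
respond in discordant directions while realising a known structural
splicing mode. Every planted effect is recorded so downstream recovery can
be measured.

Counts follow a gamma-Poisson (negative binomial) law with
``var = mu + dispersion * mu^2``; ``dispersion = 0`` degenerates to
Poisson. A gene's baseline abundance is split across its isoforms by a
Dirichlet draw, and per-sample library-size factors drawn log-uniform in
[0.5, 2] give upper-quartile normalization real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import (
    CELLS,
    CHALLENGES,
    EVENT_MODES,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    TranscriptModel,
)

#: minimum number of exons needed to realise each structural mode
_MIN_EXONS = {
    "cassette": 3,
    "tandem_cassette": 4,
    "alt3": 2,
    "alt5": 2,
    "intron_retention": 2,
    "mutually_exclusive": 3,
}

_GENE_GAP = 10_000  # bp between genes on the pseudo-chromosome


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_genes: int = 300
    #: probability over isoform counts per gene
    isoforms_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.20, 4: 0.12, 5: 0.08}
    )
    n_per_group: int = 12  # replicates per (challenge, cell) design cell
    baseline_mean: float = 150.0  # expected count per isoform
    baseline_sigma: float = 1.5  # ln-scale spread of gene abundances
    dispersion: float = 0.1
    de_fraction: float = 0.1
    frac_over: float = 0.9  # over-expression predominance among DE genes
    lfc_magnitude: float = 2.0
    as_fraction: float = 0.1  # of multi-isoform genes, planted discordant
    mode_mix: Mapping[str, float] = field(
        default_factory=lambda: {m: 1 / 6 for m in EVENT_MODES}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_fraction", "frac_over", "as_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for dist, what in (
            (self.isoforms_per_gene, "isoforms_per_gene"),
            (self.mode_mix, "mode_mix"),
        ):
            total = sum(dist.values())
            if total <= 0 or any(v < 0 for v in dist.values()):
                raise ValidationError(f"{what} is not a probability mixture")
        unknown = set(self.mode_mix) - set(EVENT_MODES)
        if unknown:
            raise ValidationError(f"unknown modes in mode_mix: {unknown}")


@dataclass
class ASTruth:
    mode: str
    up_isoform: str = ""
    down_isoform: str = ""


@dataclass
class SimulationTruth:
    """Planted effects: which genes are DE (and how) and which carry a
    discordant splicing event (and its structural mode)."""

    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> over|under
    as_genes: dict[str, ASTruth] = field(default_factory=dict)
    config: Optional[SimulationConfig] = None


# ---------------------------------------------------------------------------
# structure construction

def _base_chain(rng: np.random.Generator, start: int, n_exons: int) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for k in range(n_exons):
        # a roomy first exon absorbs the transcription-start shifts that
        # distinguish non-event isoforms
        length = int(rng.integers(180, 281)) if k == 0 else int(rng.integers(80, 201))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(250, 501))
    return exons


def _variant_for_mode(
    base: list[tuple[int, int]], mode: str, strand: str, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Exon chain differing from ``base`` by exactly one event of ``mode``.

    alt3/alt5 are planted strand-aware: the acceptor of an intron is its
    genomic-right boundary on '+' and its genomic-left boundary on '-'.
    """
    n = len(base)
    delta = 30
    if mode == "cassette":
        i = int(rng.integers(1, n - 1))
        return base[:i] + base[i + 1:]
    if mode == "tandem_cassette":
        i = int(rng.integers(1, n - 2))
        return base[:i] + base[i + 2:]
    if mode == "intron_retention":
        i = int(rng.integers(0, n - 1))
        return base[:i] + [(base[i][0], base[i + 1][1])] + base[i + 2:]
    if mode == "mutually_exclusive":
        i = int(rng.integers(1, n - 1))
        x = base[i]
        gap_start, gap_end = x[1] + 1, base[i + 1][0] - 1
        y_start = gap_start + 60
        y_end = min(y_start + 99, gap_end - 2)
        return base[:i] + [(y_start, y_end)] + base[i + 1:]
    if mode in ("alt3", "alt5"):
        i = int(rng.integers(0, n - 1))  # intron between exons i, i+1
        move_right = (mode == "alt3") == (strand == "+")
        if move_right:  # shift start of downstream exon into the intron
            s, e = base[i + 1]
            return base[:i + 1] + [(s - delta, e)] + base[i + 2:]
        s, e = base[i]  # shift end of upstream exon
        return base[:i] + [(s, e - delta)] + base[i + 1:]
    raise ValidationError(f"unknown mode {mode!r}")


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], SimulationTruth]:
    """Lay genes on a toy chromosome and build isoform structures.

    Each gene drafted for a splicing event gets a pair of isoforms differing
    by exactly the drawn structural mode; its remaining isoforms (and all
    isoforms of non-event genes) differ only by transcription-start shifts,
    which carry no splice-site signal. Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    iso_counts = sorted(config.isoforms_per_gene)
    iso_probs = np.array(
        [config.isoforms_per_gene[k] for k in iso_counts], dtype=float
    )
    iso_probs /= iso_probs.sum()
    mode_names = sorted(config.mode_mix)
    mode_probs = np.array([config.mode_mix[m] for m in mode_names], dtype=float)
    mode_probs /= mode_probs.sum()

    models: list[TranscriptModel] = []
    truth = SimulationTruth(config=config)
    cursor = 1
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        n_iso = int(rng.choice(iso_counts, p=iso_probs))
        strand = str(rng.choice(["+", "-"]))
        planted_mode = None
        if n_iso >= 2 and rng.random() < config.as_fraction:
            planted_mode = str(rng.choice(mode_names, p=mode_probs))
        min_exons = max(5, _MIN_EXONS.get(planted_mode or "", 2) + 2)
        n_exons = int(rng.integers(min_exons, min_exons + 4))
        base = _base_chain(rng, cursor, n_exons)

        chains = [base]
        if planted_mode is not None:
            chains.append(_variant_for_mode(base, planted_mode, strand, rng))
        # remaining isoforms: distinct transcription-start shifts of the base
        shift = 0
        while len(chains) < n_iso:
            shift += 10
            s, e = base[0]
            chains.append([(s + shift, e)] + base[1:])

        tids = [f"{gene_id}.{i + 1}" for i in range(len(chains))]
        for tid, chain in zip(tids, chains):
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    strand=strand,
                    exons=tuple(chain),
                )
            )
        if planted_mode is not None:
            truth.as_genes[gene_id] = ASTruth(mode=planted_mode)
        cursor = base[-1][1] + _GENE_GAP
    return models, truth


# ---------------------------------------------------------------------------
# count simulation

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    models: list[TranscriptModel],
    config: SimulationConfig,
    truth: Optional[SimulationTruth] = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw negative-binomial counts with planted challenge effects.

    DE genes multiply every isoform mean by 2^(+/-lfc) in BCG samples; for
    splicing-event genes the structural isoform pair moves discordantly (one
    up, one down) and the rest stay flat. Effects apply in both cell types
    so the two challenge contrasts see the same truth and the cell-type
    contrasts stay null. Deterministic given the config seed.
    """
    config.validate()
    if truth is None:
        truth = SimulationTruth(config=config)
    rng = np.random.default_rng(config.seed + 1)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    genes = sorted(by_gene)

    # design layout
    samples, challenge_col, cell_col = [], [], []
    for cell in CELLS:
        for challenge in CHALLENGES:
            for r in range(config.n_per_group):
                samples.append(f"{cell[:3]}_{challenge}_{r + 1:02d}")
                challenge_col.append(challenge)
                cell_col.append(cell)
    design = pd.DataFrame(
        {"challenge": challenge_col, "cell": cell_col}, index=samples
    )
    design.index.name = "sample"
    is_bcg = np.array([c == "BCG" for c in challenge_col])

    # choose DE genes among genes without a planted splicing event
    for gene in genes:
        if gene in truth.as_genes:
            continue
        if rng.random() < config.de_fraction:
            truth.de_genes[gene] = (
                "over" if rng.random() < config.frac_over else "under"
            )

    size_factors = np.exp(
        rng.uniform(np.log(0.5), np.log(2.0), size=len(samples))
    )

    unit_ids, gene_ids, rows = [], [], []
    fold = 2.0 ** config.lfc_magnitude
    for gene in genes:
        isoforms = by_gene[gene]
        n_iso = len(isoforms)
        gene_total = config.baseline_mean * n_iso * float(
            rng.lognormal(0.0, config.baseline_sigma)
        )
        shares = rng.dirichlet(np.full(n_iso, 5.0))
        iso_mu = gene_total * shares

        # planted effects on the challenge axis
        bcg_mult = np.ones(n_iso)
        if gene in truth.de_genes:
            bcg_mult[:] = fold if truth.de_genes[gene] == "over" else 1.0 / fold
        elif gene in truth.as_genes:
            # the discordant pair is the structural event pair (isoforms
            # 0 = base chain, 1 = mode variant); which one rises is random
            up, down = (0, 1) if rng.random() < 0.5 else (1, 0)
            bcg_mult[up], bcg_mult[down] = fold, 1.0 / fold
            truth.as_genes[gene].up_isoform = isoforms[up].transcript_id
            truth.as_genes[gene].down_isoform = isoforms[down].transcript_id

        for i, iso in enumerate(isoforms):
            mu = iso_mu[i] * np.where(is_bcg, bcg_mult[i], 1.0) * size_factors
            rows.append(_nb_draw(rng, mu, config.dispersion))
            unit_ids.append(iso.transcript_id)
            gene_ids.append(gene)

    values = pd.DataFrame(
        np.vstack(rows).astype(float), index=unit_ids, columns=samples
    )
    matrix = ExpressionMatrix(
        values, pd.Series(gene_ids, index=unit_ids), design
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# companion annotation resources

def simulate_gene_sets(
    genes: list[str],
    truth: SimulationTruth,
    seed: int = 0,
    n_sets: int = 25,
    n_signal_sets: int = 3,
) -> GeneSetCollection:
    """Random gene sets plus a few sets enriched with planted DE genes, so
    the over-representation and running-sum engines have signal to find."""
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    de = [g for g in genes if g in truth.de_genes]
    for i in range(n_sets):
        size = min(int(rng.integers(10, 51)), max(2, len(genes) // 2))
        members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
        sets[f"RANDOM_{i + 1:02d}"] = (f"random set {i + 1}", members)
    for i in range(n_signal_sets):
        n_de = min(len(de), int(rng.integers(8, 16)))
        if n_de < 2:
            break
        picked = list(rng.choice(de, size=n_de, replace=False))
        n_fill = min(int(rng.integers(5, 16)), max(1, len(genes) // 4))
        filler = list(rng.choice(genes, size=n_fill, replace=False))
        members = tuple(sorted(set(picked + filler)))
        sets[f"SIGNAL_{i + 1:02d}"] = (f"planted-signal set {i + 1}", members)
    return GeneSetCollection(sets, universe=tuple(genes))


def simulate_edge_list(
    genes: list[str],
    truth: SimulationTruth,
    seed: int = 0,
    background_degree: float = 1.0,
    de_extra_edges: int = 40,
    n_external_hubs: int = 5,
) -> EdgeList:
    """Random interaction edges with extra density among planted DE genes,
    standing in for a curated interaction repository.

    A few ``EXT_*`` genes absent from the expression matrix are wired to
    several DE genes each, so the one-connector rule has non-measured
    bridges to find even under the strict connector policy.
    """
    rng = np.random.default_rng(seed)
    n_bg = int(background_degree * len(genes) / 2)
    pairs = []
    for _ in range(n_bg):
        a, b = rng.choice(genes, size=2, replace=False)
        pairs.append((a, b))
    de = [g for g in genes if g in truth.de_genes]
    if len(de) >= 2:
        for _ in range(de_extra_edges):
            a, b = rng.choice(de, size=2, replace=False)
            pairs.append((a, b))
        for h in range(n_external_hubs):
            hub = f"EXT_{h + 1:02d}"
            k = min(len(de), int(rng.integers(2, 5)))
            for g in rng.choice(de, size=k, replace=False):
                pairs.append((hub, g))
    return EdgeList.from_pairs(pairs)
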
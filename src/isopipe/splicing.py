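"""Alternative-splicing candidate rule and structural event classification.

A gene is an alternative-splicing candidate in a contrast when it carries at
least two transcript isoforms, at least one is differentially expressed, and
the isoforms do not all move in one single direction: the DE signal must be
contradicted by at least one isoform that is non-DE or DE the other way.

Structural modes are read off pairs of exon chains:

* cassette / tandem cassette - one (or >=2 consecutive) internal exon(s) of
  one chain absent from the other, with the flanking exons shared and
  adjacent in the shorter chain;
* alt3 / alt5 - two chains share one boundary of an intron but differ at the
  other; resolved in transcript orientation, a difference at the acceptor
  side is alt3 and at the donor side alt5;
* intron retention - one chain has a single exon spanning exactly an
  exon-intron-exon triplet of the other;
* mutually exclusive exons - each chain holds one internal exon missing from
  the other, the two exons non-overlapping, between shared flanks.

Differences confined to the outer boundaries of first/last exons
(transcription start/end variation) trigger no mode: the taxonomy concerns
splice sites only. Identical chains classify to the empty set.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .models import ASCall, EVENT_MODES, Exon, ModeFrequencies, TranscriptModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# candidate rule

def as_candidate(statuses: Sequence[str]) -> tuple[bool, str]:
    """Apply the splicing candidate rule to one gene's isoform DE statuses.

    Returns (qualifies, direction) where direction is the DE direction
    witnessing the rule: ``over``, ``under``, ``either`` when both do, or
    ``none``.
    """
    if not statuses:
        raise UsageError("empty status list")
    bad = set(statuses) - {"over", "under", "non"}
    if bad:
        raise UsageError(f"unknown statuses {bad}")
    counts = Counter(statuses)
    n = len(statuses)
    witnesses = [
        d
        for d, opp in (("over", "under"), ("under", "over"))
        if counts[d] >= 1 and counts[opp] + counts["non"] >= 1
    ]
    if n < 2 or not witnesses:
        return False, "none"
    return True, "either" if len(witnesses) == 2 else witnesses[0]


# ---------------------------------------------------------------------------
# structural classification

def _overlap(a: Exon, b: Exon) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _skipping(long: tuple[Exon, ...], short: tuple[Exon, ...]) -> set[str]:
    """Cassette / tandem-cassette: internal run of ``long`` absent from
    ``short`` with the flanks shared and adjacent."""
    out: set[str] = set()
    sset = set(short)
    n = len(long)
    i = 1
    while i <= n - 2:
        if long[i] in sset:
            i += 1
            continue
        j = i
        while j <= n - 2 and long[j] not in sset:
            j += 1
        j -= 1  # run long[i..j] of internal exons absent from short
        left, right = long[i - 1], long[j + 1]
        if left in sset and right in sset:
            li = short.index(left)
            if li + 1 < len(short) and short[li + 1] == right:
                out.add("tandem_cassette" if j > i else "cassette")
        i = j + 2
    return out


def _mutually_exclusive(ea: tuple[Exon, ...], eb: tuple[Exon, ...]) -> set[str]:
    sa, sb = set(ea), set(eb)
    for i in range(1, len(ea) - 1):
        x = ea[i]
        if x in sb:
            continue
        left, right = ea[i - 1], ea[i + 1]
        if left not in sb or right not in sb:
            continue
        li = eb.index(left)
        if li + 2 >= len(eb) or eb[li + 2] != right:
            continue
        y = eb[li + 1]
        if y not in sa and 1 <= li + 1 <= len(eb) - 2 and not _overlap(x, y):
            return {"mutually_exclusive"}
    return set()


def _retention(container: tuple[Exon, ...], split: tuple[Exon, ...]) -> set[str]:
    """One exon of ``container`` spanning an exon-intron-exon triplet of
    ``split`` with exact flank agreement at both boundaries."""
    pair_spans = {
        (split[i][0], split[i + 1][1]) for i in range(len(split) - 1)
    }
    for exon in container:
        if exon in pair_spans:
            return {"intron_retention"}
    return set()


def _alt_sites(
    ea: tuple[Exon, ...], eb: tuple[Exon, ...], strand: str
) -> set[str]:
    out: set[str] = set()
    introns_a = [(ea[i][1], ea[i + 1][0], i) for i in range(len(ea) - 1)]
    introns_b = [(eb[i][1], eb[i + 1][0], i) for i in range(len(eb) - 1)]
    for l1, r1, ia in introns_a:
        for l2, r2, ib in introns_b:
            if l1 == l2 and r1 != r2:
                # shared upstream (genomic-left) boundary, acceptor differs
                # on '+' / donor differs on '-'; exons past the intron must
                # overlap, otherwise the difference is exon skipping
                if _overlap(ea[ia + 1], eb[ib + 1]):
                    out.add("alt3" if strand == "+" else "alt5")
            elif r1 == r2 and l1 != l2:
                if _overlap(ea[ia], eb[ib]):
                    out.add("alt5" if strand == "+" else "alt3")
    return out


def classify_event_pair(a: TranscriptModel, b: TranscriptModel) -> set[str]:
    """Structural event modes distinguishing two isoforms of one gene.

    Multiple modes may co-occur; identical chains yield the empty set.
    """
    if a.gene_id != b.gene_id:
        raise UsageError(
            f"{a.transcript_id} and {b.transcript_id} belong to different genes"
        )
    if a.strand != b.strand:
        raise UsageError(
            f"{a.transcript_id} and {b.transcript_id} are on different strands"
        )
    ea, eb = a.exons, b.exons
    if ea == eb:
        return set()
    modes = set()
    modes |= _skipping(ea, eb) | _skipping(eb, ea)
    modes |= _mutually_exclusive(ea, eb) | _mutually_exclusive(eb, ea)
    modes |= _retention(ea, eb) | _retention(eb, ea)
    modes |= _alt_sites(ea, eb, a.strand)
    if not modes:
        log.debug(
            "pair (%s, %s) differs but matches no mode",
            a.transcript_id, b.transcript_id,
        )
    return modes


# ---------------------------------------------------------------------------
# per-gene calls

def call_gene_events(
    gene_models: Sequence[TranscriptModel],
    statuses: Sequence[str],
) -> ASCall:
    """Combine the candidate rule with pairwise structural classification.

    For qualifying genes every (DE isoform, status-non-concordant isoform)
    pair is classified and the per-pair modes are unioned; evidence keeps
    the per-pair records.
    """
    if len(gene_models) != len(statuses):
        raise UsageError(
            f"{len(gene_models)} models but {len(statuses)} statuses"
        )
    if not gene_models:
        raise UsageError("no isoforms given")
    gene_ids = {m.gene_id for m in gene_models}
    if len(gene_ids) > 1:
        raise UsageError(f"models from several genes: {sorted(gene_ids)}")

    counts = Counter(statuses)
    qualifies, direction = as_candidate(list(statuses))
    modes: set[str] = set()
    evidence = []
    if qualifies:
        seen_pairs = set()
        for i, mi in enumerate(gene_models):
            if statuses[i] == "non":
                continue
            for j, mj in enumerate(gene_models):
                if i == j or statuses[j] == statuses[i]:
                    continue
                key = tuple(sorted((mi.transcript_id, mj.transcript_id)))
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                pair_modes = frozenset(classify_event_pair(mi, mj))
                if pair_modes:
                    evidence.append((key, pair_modes))
                    modes |= pair_modes
    return ASCall(
        gene_id=gene_ids.pop(),
        n_over=counts["over"],
        n_under=counts["under"],
        n_non=counts["non"],
        qualifies=qualifies,
        direction=direction,
        modes=frozenset(modes),
        evidence=tuple(evidence),
    )


def summarize_modes(calls: Iterable[ASCall]) -> ModeFrequencies:
    """Per-mode gene fractions among qualifying genes.

    Fractions may sum above one because a gene can carry several modes.
    """
    qualifying = [c for c in calls if c.qualifies]
    n = len(qualifying)
    counts = {
        mode: sum(mode in c.modes for c in qualifying) for mode in EVENT_MODES
    }
    fractions = {
        mode: (counts[mode] / n if n else 0.0) for mode in EVENT_MODES
    }
    if n == 0:
        log.warning("no qualifying genes; mode summary is empty")
    return ModeFrequencies(n_genes=n, counts=counts, fractions=fractions)
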
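"""Two-round filtration of paired-end RNA-seq alignments into guide pairs.

Round one keeps pairs whose two mates are each uniquely aligned, routing
them either to the candidate pool (mates on two different contigs — the
raw material for scaffolding connections) or to the intra-contig pool
(mates on one contig — the raw material for the median-intron estimate).

Round two re-examines the candidates against an independent realignment
(e.g. BLAT) and discards pairs that the realigner places on one contig or
that look multi-mapping above the minimal length coverage (MLC) threshold.
Survivors are the final "guide" pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import AlignmentRecord, FormatError, RealignmentRecord

logger = logging.getLogger(__name__)

__all__ = ["GuidePair", "IntraContigPair", "first_round_filter", "realign_filter"]


@dataclass(frozen=True)
class GuidePair:
    """A read pair whose mates are uniquely aligned to two different contigs."""

    read_id: str
    rec1: AlignmentRecord
    rec2: AlignmentRecord

    def __post_init__(self):
        if self.rec1.contig_id == self.rec2.contig_id:
            raise ValueError("guide pair mates must be on different contigs")
        if not (self.rec1.is_unique and self.rec2.is_unique):
            raise ValueError("guide pair mates must both be unique")


@dataclass(frozen=True)
class IntraContigPair:
    """A pair with both mates on one contig; the inner region is an intron
    candidate used for the median-intron estimate.

    ``inner_start``/``inner_end`` delimit the region between the two mate
    alignments (0-based half-open); abutting or overlapping mates give an
    empty region.
    """

    read_id: str
    contig_id: str
    inner_start: int
    inner_end: int

    @property
    def inner_length(self) -> int:
        return self.inner_end - self.inner_start


def _mate_is_unique(records: Sequence[AlignmentRecord]) -> bool:
    return len(records) == 1 and records[0].is_unique


def first_round_filter(
    pair_stream: Mapping[str, Mapping[int, Sequence[AlignmentRecord]]],
    require_fr: bool = True,
) -> tuple[list[GuidePair], list[IntraContigPair]]:
    """Split uniquely-aligned pairs into cross-contig candidates and
    same-contig intron evidence.

    Every input pair lands in exactly one of {candidate, intra, dropped}:
    pairs with any non-unique or unmapped mate are dropped; unique pairs on
    two contigs become candidates; unique pairs on one contig become
    :class:`IntraContigPair` records, subject (by default) to FR
    consistency — opposite strands with the leftmost mate on ``+`` — which
    excludes chimeric artifacts from the intron pool.
    """
    candidates: list[GuidePair] = []
    intra: list[IntraContigPair] = []
    for read_id, mates in pair_stream.items():
        extra = set(mates) - {1, 2}
        if extra:
            raise FormatError(f"read {read_id!r} reports mate indices {sorted(mates)}")
        recs1 = mates.get(1, [])
        recs2 = mates.get(2, [])
        if not (_mate_is_unique(recs1) and _mate_is_unique(recs2)):
            continue
        r1, r2 = recs1[0], recs2[0]
        if r1.contig_id != r2.contig_id:
            candidates.append(GuidePair(read_id=read_id, rec1=r1, rec2=r2))
            continue
        up, down = (r1, r2) if r1.start <= r2.start else (r2, r1)
        if require_fr and not (up.strand == "+" and down.strand == "-"):
            continue
        inner_start = up.end
        inner_end = max(up.end, down.start)
        intra.append(
            IntraContigPair(
                read_id=read_id,
                contig_id=r1.contig_id,
                inner_start=inner_start,
                inner_end=inner_end,
            )
        )
    return candidates, intra


def realign_filter(
    candidates: Sequence[GuidePair],
    realignments: Sequence[RealignmentRecord] | None,
    mlc: float,
) -> list[GuidePair]:
    """Re-filter candidates using second-round realignments and MLC.

    A candidate is discarded when (a) any realignment places both of its
    mates on a common contig, or (b) either mate has realignments with
    coverage >= *mlc* on two or more distinct contigs (a multi-contig,
    hence ambiguous, mate).  Candidates with no realignment records are
    kept: absence of contrary evidence.  With ``realignments=None`` the
    filter is skipped entirely (identity) with a warning.
    """
    if realignments is None:
        logger.warning("no realignments supplied; second-round re-filtration skipped")
        return list(candidates)

    by_mate: dict[tuple[str, int], list[RealignmentRecord]] = {}
    for rec in realignments:
        by_mate.setdefault((rec.read_id, rec.mate), []).append(rec)

    guides: list[GuidePair] = []
    for cand in candidates:
        recs1 = by_mate.get((cand.read_id, 1), [])
        recs2 = by_mate.get((cand.read_id, 2), [])
        contigs1 = {r.contig_id for r in recs1}
        contigs2 = {r.contig_id for r in recs2}
        if contigs1 & contigs2:
            continue  # realigner sees both mates on one contig
        ambiguous = False
        for recs in (recs1, recs2):
            strong = {r.contig_id for r in recs if r.coverage >= mlc}
            if len(strong) >= 2:
                ambiguous = True
                break
        if ambiguous:
            continue
        guides.append(cand)
    return guides
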
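"""Gap-size estimation and scaffold sequence emission.

The genome-wide median intron length is estimated from pairs whose two
mates landed on a single contig: the region between the two mate
alignments is an intron candidate.  At each scaffold junction, if the
connection's minimal inserted size is smaller than that median, the gap is
filled with the difference in Ns (the missing part of a typical intron);
otherwise a fixed run of 100 Ns marks a gap of unknown size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .evaluate import n50
from .formats import AgpRow, ContigSet, FormatError, revcomp, write_agp, write_fasta
from .graph import ScaffoldPath
from .guide_filter import IntraContigPair

logger = logging.getLogger(__name__)

__all__ = ["GapModel", "estimate_median_intron", "gap_size", "emit_scaffolds", "ScaffoldAssembly"]


@dataclass(frozen=True)
class GapModel:
    """Junction gap model: the estimated median intron size M (bp) and the
    default gap used when the minimal inserted size already exceeds M."""

    median_intron: int
    default_gap: int = 100

    def __post_init__(self):
        if self.median_intron < 0:
            raise ValueError("median_intron must be >= 0")
        if self.default_gap <= 0:
            raise ValueError("default_gap must be positive")


def estimate_median_intron(
    intra: Sequence[IntraContigPair],
    default_gap: int = 100,
    min_inner_length: int = 0,
) -> GapModel:
    """Median inner-region length over all intra-contig pairs.

    Even-count medians take the lower middle value, keeping the result an
    integer and deterministic.  With no usable pairs the median is 0 and a
    warning is logged — every junction then receives the default gap.

    min_inner_length
        Optionally drop pairs with inner regions shorter than this from
        the intron pool (0 keeps all, including overlapping mates).
    """
    lengths = sorted(p.inner_length for p in intra if p.inner_length >= min_inner_length)
    if not lengths:
        logger.warning("no intra-contig pairs: median intron set to 0, all gaps default")
        return GapModel(median_intron=0, default_gap=default_gap)
    return GapModel(median_intron=lengths[(len(lengths) - 1) // 2], default_gap=default_gap)


def gap_size(min_insert: int, model: GapModel) -> int:
    """N-run length for one junction.

    ``median - min_insert`` when the minimal inserted size is strictly
    smaller than the median intron, else the default gap.
    """
    if min_insert < 0:
        raise ValueError("min_insert must be >= 0")
    if min_insert < model.median_intron:
        return model.median_intron - min_insert
    return model.default_gap


@dataclass
class ScaffoldAssembly:
    """Emitted scaffolds: sequences, AGP structure and a summary report."""

    sequences: dict[str, str]
    agp_rows: list[AgpRow]
    paths: list[ScaffoldPath]
    gaps: list[list[int]]  # per path, per junction
    report: dict = field(default_factory=dict)

    def write(self, fasta_path: str | Path | None = None, agp_path: str | Path | None = None) -> None:
        if fasta_path is not None:
            write_fasta(fasta_path, self.sequences.items())
        if agp_path is not None:
            write_agp(agp_path, self.agp_rows)


def emit_scaffolds(
    paths: Sequence[ScaffoldPath],
    contigs: ContigSet,
    model: GapModel,
    name_prefix: str = "scaffold",
) -> ScaffoldAssembly:
    """Materialise scaffold sequences and their AGP description.

    Each path's sequence is its oriented contig sequences (``-`` contigs
    reverse-complemented) joined by N-runs of the per-junction gap size.
    Non-N bases are conserved: they sum exactly to the total contig length.
    """
    sequences: dict[str, str] = {}
    agp_rows: list[AgpRow] = []
    all_gaps: list[list[int]] = []
    for i, path in enumerate(paths, 1):
        name = f"{name_prefix}_{i}"
        pieces: list[str] = []
        pos = 0  # 0-based cursor in the scaffold
        part = 0
        gaps: list[int] = []
        for j, (cid, orient) in enumerate(path.contigs):
            if cid not in contigs:
                raise FormatError(f"scaffold references unknown contig {cid!r}")
            seq = contigs.sequence(cid)
            if orient == "-":
                seq = revcomp(seq)
            part += 1
            agp_rows.append(
                AgpRow(
                    object=name, object_beg=pos + 1, object_end=pos + len(seq),
                    part_number=part, component_type="W", component_id=cid,
                    component_beg=1, component_end=len(seq), orientation=orient,
                )
            )
            pieces.append(seq)
            pos += len(seq)
            if j < len(path.junctions):
                gap = gap_size(path.junctions[j].min_insert, model)
                gaps.append(gap)
                part += 1
                agp_rows.append(
                    AgpRow(
                        object=name, object_beg=pos + 1, object_end=pos + gap,
                        part_number=part, component_type="N", gap_length=gap,
                    )
                )
                pieces.append("N" * gap)
                pos += gap
        sequences[name] = "".join(pieces)
        all_gaps.append(gaps)

    contig_lengths = list(contigs.lengths().values())
    scaffold_lengths = [len(s) for s in sequences.values()]
    report = {
        "n_contigs": len(contigs),
        "n_scaffolds": len(sequences),
        "n_junctions": sum(len(p.junctions) for p in paths),
        "total_contig_length": contigs.total_length(),
        "total_scaffold_length": sum(scaffold_lengths),
        "median_intron": model.median_intron,
        "n50_before": n50(contig_lengths) if contig_lengths else 0,
        "n50_after": n50(scaffold_lengths) if scaffold_lengths else 0,
    }
    return ScaffoldAssembly(sequences=sequences, agp_rows=agp_rows, paths=list(paths), gaps=all_gaps, report=report)
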
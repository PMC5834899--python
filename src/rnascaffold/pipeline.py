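"""End-to-end scaffolding pipeline: alignments in, scaffolds out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import emit as _emit
from . import graph as _graph
from .emit import GapModel, ScaffoldAssembly
from .formats import ContigSet, Params, read_contigs, read_psl, read_sam_pairs, write_connections_tsv
from .guide_filter import GuidePair, IntraContigPair, first_round_filter, realign_filter
from .graph import Connection, ScaffoldPath

__all__ = ["ScaffoldResult", "scaffold", "scaffold_files"]


@dataclass
class ScaffoldResult:
    """Everything one scaffolding run produced."""

    contigs: ContigSet
    params: Params
    guides: list[GuidePair]
    intra: list[IntraContigPair]
    connections: list[Connection]  # aggregated, pre-optimisation
    survivors: list[Connection]  # after per-end optimisation
    paths: list[ScaffoldPath]
    gap_model: GapModel
    assembly: ScaffoldAssembly
    stats: dict = field(default_factory=dict)

    def write(self, prefix: str | Path) -> None:
        """Write scaffold FASTA, AGP and the connection TSV under *prefix*."""
        prefix = Path(prefix)
        self.assembly.write(fasta_path=prefix.with_suffix(".fasta"), agp_path=prefix.with_suffix(".agp"))
        gaps = {c.key(): _emit.gap_size(c.min_insert, self.gap_model) for c in self.survivors}
        write_connections_tsv(prefix.with_suffix(".connections.tsv"), self.survivors, gaps)


def scaffold(
    contigs: ContigSet,
    pair_stream,
    realignments=None,
    params: Params | None = None,
    skip_realign_filter: bool = False,
) -> ScaffoldResult:
    """Run the scaffolder on pre-parsed alignments.

    *pair_stream* is the mapping produced by
    :func:`rnascaffold.formats.read_sam_pairs`; *realignments* the record
    list from :func:`rnascaffold.formats.read_psl`, or None to skip the
    second-round re-filtration.
    """
    params = params or Params()
    candidates, intra = first_round_filter(pair_stream)
    if skip_realign_filter:
        realignments = None
    guides = realign_filter(candidates, realignments, params.mlc)

    raw = [_graph.make_connection(g, contigs) for g in guides]
    passing = _graph.filter_by_mil(raw, params.mil)
    connections = _graph.aggregate(passing, params.min_pairs)
    survivors = _graph.select_optimal(connections)
    paths = _graph.build_paths(survivors, contigs.ids)

    gap_model = _emit.estimate_median_intron(intra, default_gap=params.default_gap)
    assembly = _emit.emit_scaffolds(paths, contigs, gap_model)
    stats = {
        "n_pairs": len(pair_stream),
        "n_candidates": len(candidates),
        "n_intra": len(intra),
        "n_guides": len(guides),
        "n_connections_raw": len(raw),
        "n_connections_mil": len(passing),
        "n_connections": len(connections),
        "n_survivors": len(survivors),
        **assembly.report,
    }
    return ScaffoldResult(
        contigs=contigs, params=params, guides=guides, intra=intra,
        connections=connections, survivors=survivors, paths=paths,
        gap_model=gap_model, assembly=assembly, stats=stats,
    )


def scaffold_files(
    contig_fasta: str | Path,
    sam_path: str | Path,
    psl_path: str | Path | None = None,
    params: Params | None = None,
    uniqueness_rule: str = "tag",
) -> ScaffoldResult:
    """File-level convenience wrapper around :func:`scaffold`."""
    contigs = read_contigs(contig_fasta)
    pair_stream = read_sam_pairs(sam_path, contigs, uniqueness_rule=uniqueness_rule)
    realignments = read_psl(psl_path) if psl_path is not None else None
    return scaffold(contigs, pair_stream, realignments, params)
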
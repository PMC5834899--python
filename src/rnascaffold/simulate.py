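"""Synthetic transcribed-genome generator for end-to-end offline testing.

The generator builds a small genome of one or more units (chromosomes)
carrying non-overlapping multi-exon genes on both strands, fragments it
into contigs — preferentially breaking inside introns so that transcripts
span the breaks — and simulates FR-oriented paired-end RNA-seq reads whose
fragments are drawn from the spliced transcripts.  Reads are projected
through the exon chain back onto contig coordinates, producing spliced SAM
records (with ``N`` operations where a read crosses an intron retained
inside one contig) and matching PSL realignment records.  Truth tables
(contig placements, true junctions, per-pair placements) make every
downstream module checkable bit-for-bit.

Noise knobs: a fraction of pairs can have one mate re-assigned to a random
wrong position (emulating mis-mapped pairs, the source of spurious
weight-1 connections), and a fraction of mates can be emitted as
multi-mappers that the uniqueness rule must exclude.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluate import TruthPlacement, write_truth_tsv
from .formats import ContigSet, write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Gene",
    "TrueJunction",
    "SimMate",
    "SimPair",
    "Simulation",
    "simulate_genome",
    "fragment_contigs",
    "simulate_pairs",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic harness.

    Exon lengths are drawn log-uniformly around a median of 170 bp, the
    typical metazoan exon size; intron lengths likewise around their own
    configurable median.  Breaks are placed inside introns with
    probability ``break_preference`` so that spliced read pairs can span
    the resulting contig junctions.
    """

    seed: int = 0
    n_units: int = 5
    unit_length: int = 100_000
    n_genes_per_unit: int = 40
    exon_median: int = 170
    exon_spread: float = 1.4  # log-uniform factor around the median
    exon_min: int = 120
    exon_max: int = 400
    intron_median: int = 400
    intron_spread: float = 2.0
    intron_min: int = 120
    intron_max: int = 2_000
    exons_per_gene_min: int = 3
    exons_per_gene_max: int = 5
    min_intergenic: int = 50
    n_contig_breaks: int = 199
    break_preference: float = 1.0
    min_break_spacing: int = 400
    read_length: int = 100
    fragment_min: int = 250
    fragment_max: int = 500
    pairs_per_junction: int = 10
    background_pairs_per_gene: int = 3
    noise_fraction: float = 0.0
    multimap_fraction: float = 0.0

    def __post_init__(self):
        for name in ("n_units", "unit_length", "n_genes_per_unit", "n_contig_breaks",
                     "read_length", "pairs_per_junction", "background_pairs_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("break_preference", "noise_fraction", "multimap_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fragment_min < self.read_length:
            raise ValueError("fragment_min must be >= read_length")
        if self.fragment_max < self.fragment_min:
            raise ValueError("fragment_max < fragment_min")

    def write(self, path: str | Path) -> None:
        """Persist the configuration as a plain key=value file."""
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")


@dataclass
class Gene:
    gene_id: str
    unit_id: str
    strand: str
    exons: list[tuple[int, int]]  # genome coords, sorted, half-open

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class TrueJunction:
    """Adjacent contigs on one unit; fragmentation loses no sequence, so
    the true inter-contig distance is zero."""

    left_contig: str
    right_contig: str
    unit_id: str
    position: int  # break position on the unit
    distance: int = 0


@dataclass
class SimMate:
    contig_id: str
    strand: str
    blocks: list[tuple[int, int]]  # contig coords, ascending

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class SimPair:
    read_id: str
    mate1: SimMate
    mate2: SimMate
    kind: str  # "junction", "background" or "noise"
    junction: tuple[str, str] | None = None
    multimapped: tuple[bool, bool] = (False, False)
    extra_psl_contig: str | None = None  # second above-MLC hit for noise mates
    noisy_mate: int | None = None


@dataclass
class Simulation:
    """Everything one simulation run produced, plus its writers."""

    config: SimConfig
    units: dict[str, str]
    genes: list[Gene]
    contigs: ContigSet
    truth: dict[str, TruthPlacement]
    junctions: list[TrueJunction]
    pairs: list[SimPair]
    unreachable_junctions: list[TrueJunction] = field(default_factory=list)

    def write_genome_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.units.items())

    def write_contig_fasta(self, path: str | Path) -> None:
        write_fasta(path, ((cid, self.contigs.sequence(cid)) for cid in self.contigs.ids))

    def write_truth_tsv(self, path: str | Path) -> None:
        write_truth_tsv(path, self.truth.values())

    def write_junctions_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("left_contig\tright_contig\tunit_id\tposition\tdistance\n")
            for j in self.junctions:
                fh.write(f"{j.left_contig}\t{j.right_contig}\t{j.unit_id}\t{j.position}\t{j.distance}\n")

    def write_sam(self, path: str | Path) -> None:
        write_sam(path, self.contigs, self.pairs)

    def write_psl(self, path: str | Path) -> None:
        write_psl(path, self.contigs, self.pairs)


# ---------------------------------------------------------------------------
# genome


def _draw_lengths(rng: np.random.Generator, n: int, median: int, spread: float,
                  lo: int, hi: int) -> np.ndarray:
    """Log-uniform lengths around *median* (its sample median), clipped."""
    factors = np.exp(rng.uniform(-np.log(spread), np.log(spread), size=n))
    return np.clip(np.rint(median * factors).astype(int), lo, hi)


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[Gene]]:
    """Generate unit sequences with non-overlapping multi-exon genes.

    Gene structures are drawn first; if their total extent plus minimal
    intergenic spacing does not fit the unit, generation aborts with
    advice to lower the gene density.  Remaining slack is distributed
    randomly over the intergenic gaps.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    units: dict[str, str] = {}
    genes: list[Gene] = []
    for u in range(config.n_units):
        unit_id = f"unit_{u:02d}"
        seq = _BASES[rng.integers(0, 4, size=config.unit_length)].tobytes().decode()
        units[unit_id] = seq
        structures = []
        for g in range(config.n_genes_per_unit):
            n_exons = int(rng.integers(config.exons_per_gene_min, config.exons_per_gene_max + 1))
            exon_lens = _draw_lengths(rng, n_exons, config.exon_median, config.exon_spread,
                                      config.exon_min, config.exon_max)
            intron_lens = _draw_lengths(rng, n_exons - 1, config.intron_median, config.intron_spread,
                                        config.intron_min, config.intron_max)
            structures.append((exon_lens, intron_lens))
        total_extent = sum(int(e.sum() + i.sum()) for e, i in structures)
        n_gaps = config.n_genes_per_unit + 1
        slack = config.unit_length - total_extent - n_gaps * config.min_intergenic
        if slack < 0:
            raise ValueError(
                "genes cannot be placed without overlap: lower n_genes_per_unit "
                "or gene sizes, or raise unit_length"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1)) if n_gaps > 1 else np.array([], int)
        gap_extra = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for g, (exon_lens, intron_lens) in enumerate(structures):
            pos += config.min_intergenic + int(gap_extra[g])
            exons = []
            cursor = pos
            for i, el in enumerate(exon_lens):
                exons.append((cursor, cursor + int(el)))
                cursor += int(el)
                if i < len(intron_lens):
                    cursor += int(intron_lens[i])
            pos = cursor
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gene_id=f"{unit_id}_g{g:03d}", unit_id=unit_id, strand=strand, exons=exons))
    return units, genes


# ---------------------------------------------------------------------------
# fragmentation


def fragment_contigs(
    units: dict[str, str], genes: Sequence[Gene], config: SimConfig
) -> tuple[ContigSet, dict[str, TruthPlacement], list[TrueJunction]]:
    """Fragment the units into contigs at (preferentially intronic) breaks.

    Concatenating the contigs of a unit in rank order reconstructs the
    unit exactly — no sequence is lost, so true junction distances are 0.
    """
    rng = np.random.default_rng(config.seed + 1)
    # draw intronic breaks from distinct introns: a second break in the same
    # intron would create a pure-intron sliver contig no transcript can reach
    introns = [(g.unit_id, s, e) for g in genes for s, e in g.introns if e - s > 2]
    rng.shuffle(introns)
    unit_ids = list(units)
    unit_lengths = np.array([len(units[u]) for u in unit_ids], dtype=float)
    breaks: dict[str, list[int]] = {u: [] for u in unit_ids}

    def spaced(u: str, pos: int) -> bool:
        return all(abs(pos - b) >= config.min_break_spacing for b in breaks[u]) and (
            config.min_break_spacing <= pos <= len(units[u]) - config.min_break_spacing
        )

    for _ in range(config.n_contig_breaks):
        placed = False
        for _try in range(200):
            if introns and rng.random() < config.break_preference:
                u, s, e = introns.pop()
                pos = int(rng.integers(s + 1, e))
                if not spaced(u, pos):
                    continue  # intron is spent either way
            else:
                u = unit_ids[int(rng.choice(len(unit_ids), p=unit_lengths / unit_lengths.sum()))]
                pos = int(rng.integers(1, len(units[u])))
                if not spaced(u, pos):
                    continue
            breaks[u].append(pos)
            placed = True
            break
        if not placed:
            logger.warning("could not place a break with the required spacing; emitting fewer contigs")

    seqs: dict[str, str] = {}
    truth: dict[str, TruthPlacement] = {}
    junctions: list[TrueJunction] = []
    idx = 0
    for u in unit_ids:
        bounds = [0] + sorted(breaks[u]) + [len(units[u])]
        prev_name = None
        for rank, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            name = f"ctg_{idx:05d}"
            idx += 1
            seqs[name] = units[u][s:e]
            truth[name] = TruthPlacement(
                contig_id=name, unit_id=u, unit_kind="chromosome",
                start=s, end=e, strand="+", rank=rank,
            )
            if prev_name is not None:
                junctions.append(TrueJunction(left_contig=prev_name, right_contig=name, unit_id=u, position=s))
            prev_name = name
    return ContigSet(seqs), truth, junctions


# ---------------------------------------------------------------------------
# read pairs


class _ContigIndex:
    """Map unit coordinates to (contig, offset)."""

    def __init__(self, truth: dict[str, TruthPlacement]):
        self.by_unit: dict[str, tuple[list[int], list[TruthPlacement]]] = {}
        for p in truth.values():
            starts, places = self.by_unit.setdefault(p.unit_id, ([], []))
            places.append(p)
        for unit, (starts, places) in self.by_unit.items():
            places.sort(key=lambda p: p.start)
            starts[:] = [p.start for p in places]

    def locate(self, unit: str, start: int, end: int) -> tuple[str, int, int] | None:
        """Contig-space interval for a unit interval fully inside one contig."""
        starts, places = self.by_unit[unit]
        i = bisect_right(starts, start) - 1
        p = places[i]
        if end > p.end:
            return None
        return p.contig_id, start - p.start, end - p.start


def _project(gene: Gene, t0: int, t1: int) -> list[tuple[int, int]]:
    """Project a transcript interval through the exon chain to genome blocks.

    Transcript coordinates run 5'→3' on the gene strand; returned genome
    blocks are ascending.
    """
    if not (0 <= t0 < t1 <= gene.transcript_length):
        raise ValueError("transcript interval out of range")
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    blocks: list[tuple[int, int]] = []
    cursor = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(t0, cursor), min(t1, cursor + length)
        if lo < hi:
            if gene.strand == "+":
                blocks.append((s + (lo - cursor), s + (hi - cursor)))
            else:
                blocks.append((e - (hi - cursor), e - (lo - cursor)))
        cursor += length
    blocks.sort()
    return blocks


def _transcript_split(gene: Gene, break_pos: int) -> int | None:
    """Transcript coordinate separating exon sequence 5' of the break from
    sequence 3' of it, or None when the break is not inside this gene's
    intron span."""
    if not any(s < break_pos < e for s, e in gene.introns):
        return None
    left = sum(e - s for s, e in gene.exons if e <= break_pos)
    if gene.strand == "+":
        return left
    return gene.transcript_length - left


def _mate_for(gene: Gene, t0: int, t1: int, index: _ContigIndex, mate: int) -> SimMate | None:
    genome_blocks = _project(gene, t0, t1)
    g0, g1 = genome_blocks[0][0], genome_blocks[-1][1]
    located = index.locate(gene.unit_id, g0, g1)
    if located is None:
        return None
    contig, off0, _ = located
    shift = genome_blocks[0][0] - off0
    blocks = [(s - shift, e - shift) for s, e in genome_blocks]
    # mate 1 reads the transcript strand, mate 2 the opposite (FR geometry)
    strand = gene.strand if mate == 1 else ("-" if gene.strand == "+" else "+")
    return SimMate(contig_id=contig, strand=strand, blocks=blocks)


def simulate_pairs(
    units: dict[str, str],
    genes: Sequence[Gene],
    contigs: ContigSet,
    truth: dict[str, TruthPlacement],
    junctions: Sequence[TrueJunction],
    config: SimConfig,
) -> tuple[list[SimPair], list[TrueJunction]]:
    """Draw FR read pairs from spliced transcripts.

    For every true junction spanned by some gene's intron, fragments are
    positioned so that mate 1 and mate 2 land cleanly on the two adjacent
    contigs, yielding ``pairs_per_junction`` guide pairs.  Additional
    background fragments per gene populate the same-contig (intron-pool)
    evidence.  Noise and multi-mapping are then applied pair-wise.
    Junctions no transcript can span are returned for the caller to warn
    about.
    """
    rng = np.random.default_rng(config.seed + 2)
    index = _ContigIndex(truth)
    rl = config.read_length
    pairs: list[SimPair] = []
    unreachable: list[TrueJunction] = []

    genes_by_unit: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_unit.setdefault(g.unit_id, []).append(g)

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"read_{counter:07d}"

    for junction in junctions:
        spanning = [
            (g, _transcript_split(g, junction.position))
            for g in genes_by_unit.get(junction.unit_id, [])
        ]
        spanning = [(g, t) for g, t in spanning if t is not None]
        made = 0
        tries = 0
        while made < config.pairs_per_junction and tries < 60 * config.pairs_per_junction:
            tries += 1
            if not spanning:
                break
            g, t_split = spanning[int(rng.integers(len(spanning)))]
            frag = int(rng.integers(config.fragment_min, config.fragment_max + 1))
            frag = min(frag, g.transcript_length)
            lo = max(0, t_split - frag + rl)
            hi = min(g.transcript_length - frag, t_split - rl)
            if hi < lo:
                continue
            t0 = int(rng.integers(lo, hi + 1))
            m1 = _mate_for(g, t0, t0 + rl, index, 1)
            m2 = _mate_for(g, t0 + frag - rl, t0 + frag, index, 2)
            if m1 is None or m2 is None:
                continue
            want = {junction.left_contig, junction.right_contig}
            if {m1.contig_id, m2.contig_id} != want:
                continue
            pairs.append(
                SimPair(read_id=next_id(), mate1=m1, mate2=m2, kind="junction",
                        junction=(junction.left_contig, junction.right_contig))
            )
            made += 1
        if made == 0 and config.pairs_per_junction > 0:
            unreachable.append(junction)
    if unreachable:
        logger.warning(
            "%d junction(s) cannot be spanned by any simulated fragment", len(unreachable)
        )

    for g in genes:
        if g.transcript_length < config.fragment_min:
            continue
        for _ in range(config.background_pairs_per_gene):
            frag = int(rng.integers(config.fragment_min, min(config.fragment_max, g.transcript_length) + 1))
            if g.transcript_length < frag:
                continue
            t0 = int(rng.integers(0, g.transcript_length - frag + 1))
            m1 = _mate_for(g, t0, t0 + rl, index, 1)
            m2 = _mate_for(g, t0 + frag - rl, t0 + frag, index, 2)
            if m1 is None or m2 is None:
                continue
            pairs.append(SimPair(read_id=next_id(), mate1=m1, mate2=m2, kind="background"))

    # noise: re-assign one mate of a fraction of pairs to a wrong position
    contig_ids = contigs.ids
    for p in pairs:
        if config.noise_fraction and rng.random() < config.noise_fraction:
            which = 1 if rng.random() < 0.5 else 2
            victim = p.mate1 if which == 1 else p.mate2
            for _ in range(50):
                wrong = contig_ids[int(rng.integers(len(contig_ids)))]
                if wrong != p.mate1.contig_id and wrong != p.mate2.contig_id and contigs.length(wrong) > rl:
                    break
            else:
                continue
            start = int(rng.integers(0, contigs.length(wrong) - rl + 1))
            fake = SimMate(contig_id=wrong, strand=victim.strand, blocks=[(start, start + rl)])
            if which == 1:
                p.mate1 = fake
            else:
                p.mate2 = fake
            p.kind = "noise"
            p.junction = None
            p.noisy_mate = which
            if rng.random() < 0.5:
                # give the noise mate a second strong realignment hit so the
                # MLC filter has true positives to remove
                others = [c for c in contig_ids if c != wrong and contigs.length(c) > rl]
                if others:
                    p.extra_psl_contig = others[int(rng.integers(len(others)))]

    # multi-mapping: emit a fraction of mates with a second placement
    for p in pairs:
        mm1 = bool(config.multimap_fraction and rng.random() < config.multimap_fraction)
        mm2 = bool(config.multimap_fraction and rng.random() < config.multimap_fraction)
        p.multimapped = (mm1, mm2)

    return pairs, unreachable


# ---------------------------------------------------------------------------
# emission


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _mate_seq(contigs: ContigSet, mate: SimMate) -> str:
    # SAM stores SEQ on the forward reference strand, so the aligned block
    # sequence is emitted as-is regardless of the mate's strand
    return "".join(contigs.sequence(mate.contig_id)[s:e] for s, e in mate.blocks)


def write_sam(path: str | Path, contigs: ContigSet, pairs: Sequence[SimPair]) -> None:
    """Emit the simulated placements as a SAM file with NH tags.

    Multi-mapped mates get a second (secondary) random placement and
    ``NH:i:2`` on both records.
    """
    rng = np.random.default_rng(0xC0FFEE)  # secondary placements only
    contig_ids = contigs.ids
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for cid in contig_ids:
            fh.write(f"@SQ\tSN:{cid}\tLN:{contigs.length(cid)}\n")
        for p in pairs:
            for mate_no, mate, other in ((1, p.mate1, p.mate2), (2, p.mate2, p.mate1)):
                multi = p.multimapped[mate_no - 1]
                nh = 2 if multi else 1
                flag = 0x1 | (0x40 if mate_no == 1 else 0x80)
                if mate.strand == "-":
                    flag |= 0x10
                if other.strand == "-":
                    flag |= 0x20
                seq = _mate_seq(contigs, mate)
                rnext = "=" if other.contig_id == mate.contig_id else other.contig_id
                fh.write(
                    "\t".join(
                        [
                            p.read_id, str(flag), mate.contig_id, str(mate.start + 1), "60",
                            _cigar(mate.blocks), rnext, str(other.start + 1),
                            "0", seq, "I" * len(seq), f"NH:i:{nh}",
                        ]
                    )
                    + "\n"
                )
                if multi:
                    rl = sum(e - s for s, e in mate.blocks)
                    for _ in range(50):
                        alt = contig_ids[int(rng.integers(len(contig_ids)))]
                        if contigs.length(alt) > rl:
                            break
                    else:
                        continue
                    astart = int(rng.integers(0, contigs.length(alt) - rl + 1))
                    fh.write(
                        "\t".join(
                            [
                                p.read_id, str(flag | 0x100), alt, str(astart + 1), "0",
                                f"{rl}M", "*", "0", "0", "*", "*", f"NH:i:{nh}",
                            ]
                        )
                        + "\n"
                    )


def write_psl(path: str | Path, contigs: ContigSet, pairs: Sequence[SimPair]) -> None:
    """Emit realignment records mirroring the SAM placements (coverage 1)
    as headerless PSL; noise mates may carry a second above-MLC hit."""
    with open(path, "w") as fh:
        for p in pairs:
            for mate_no, mate in ((1, p.mate1), (2, p.mate2)):
                rl = sum(e - s for s, e in mate.blocks)
                _write_psl_line(fh, p.read_id, mate_no, mate.contig_id, contigs.length(mate.contig_id),
                                mate.blocks, mate.strand, rl, rl)
                if p.noisy_mate == mate_no and p.extra_psl_contig is not None:
                    alt_len = contigs.length(p.extra_psl_contig)
                    matches = max(1, int(round(0.95 * rl)))
                    _write_psl_line(fh, p.read_id, mate_no, p.extra_psl_contig, alt_len,
                                    [(0, matches)], mate.strand, matches, rl)


def _write_psl_line(fh, read_id, mate_no, t_name, t_size, blocks, strand, matches, q_size):
    t_start, t_end = blocks[0][0], blocks[-1][1]
    block_sizes = ",".join(str(e - s) for s, e in blocks) + ","
    q_starts = []
    q = 0
    for s, e in blocks:
        q_starts.append(q)
        q += e - s
    fields = [
        matches, 0, 0, 0, 0, 0, len(blocks) - 1, t_end - t_start - matches, strand,
        f"{read_id}/{mate_no}", q_size, 0, matches, t_name, t_size, t_start, t_end,
        len(blocks), block_sizes, ",".join(map(str, q_starts)) + ",",
        ",".join(str(s) for s, _ in blocks) + ",",
    ]
    fh.write("\t".join(str(f) for f in fields) + "\n")


def simulate_all(config: SimConfig) -> Simulation:
    """Run the full generator: genome → contigs → read pairs."""
    units, genes = simulate_genome(config)
    contigs, truth, junctions = fragment_contigs(units, genes, config)
    pairs, unreachable = simulate_pairs(units, genes, contigs, truth, junctions, config)
    return Simulation(
        config=config, units=units, genes=genes, contigs=contigs, truth=truth,
        junctions=junctions, pairs=pairs, unreachable_junctions=unreachable,
    )
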
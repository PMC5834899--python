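"""Readers and writers for the file formats the scaffolding pipeline touches.

All coordinates are normalised to a single internal convention: 0-based,
half-open ``[start, end)`` intervals on the forward strand of the sequence
they refer to.  SAM input (1-based) is converted at the boundary; PSL is
already 0-based and is kept as-is.

Formats handled here:

* FASTA  — contigs in, scaffold sequences out (via :func:`write_fasta`)
* SAM    — first-round spliced paired-end alignments in (through pysam)
* PSL    — second-round realignments in (21-column BLAT output)
* AGP    — scaffold structure out (AGP v2.1)
* TSV    — connection tables out
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ContigSet",
    "AlignmentRecord",
    "RealignmentRecord",
    "Params",
    "read_contigs",
    "read_sam_pairs",
    "read_psl",
    "write_fasta",
    "write_agp",
    "read_agp",
    "reconstruct_from_agp",
    "write_connections_tsv",
    "revcomp",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ContigSet:
    """An id-addressable collection of contig sequences.

    Ids are unique and non-empty; sequences are stored uppercased and every
    contig has positive length.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for cid, seq in sequences.items():
            if not cid:
                raise FormatError("empty contig id")
            if cid in self._seqs:
                raise FormatError(f"duplicate id: {cid!r}")
            seq = seq.upper()
            if not seq:
                raise FormatError(f"empty sequence for contig {cid!r}")
            self._seqs[cid] = seq

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, cid: str) -> bool:
        return cid in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, cid: str) -> str:
        return self._seqs[cid]

    def length(self, cid: str) -> int:
        return len(self._seqs[cid])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self._seqs.items()}


@dataclass(frozen=True)
class AlignmentRecord:
    """One mate's placement on one contig (first-round evidence).

    ``start``/``end`` are 0-based half-open reference coordinates; ``end``
    is computed from the CIGAR reference span, so deletions and skipped
    introns (``N``) are included.
    """

    read_id: str
    mate: int
    contig_id: str
    strand: str
    start: int
    end: int
    aligned_query_bases: int
    query_length: int
    is_unique: bool

    def __post_init__(self):
        if self.mate not in (1, 2):
            raise FormatError(f"mate must be 1 or 2, got {self.mate}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"bad interval [{self.start}, {self.end})")
        if self.aligned_query_bases > self.query_length:
            raise FormatError("aligned_query_bases exceeds query_length")
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class RealignmentRecord:
    """One mate's second-round realignment with its query coverage."""

    read_id: str
    mate: int
    contig_id: str
    coverage: float
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if not (0.0 <= self.coverage <= 1.0):
            raise FormatError(f"coverage out of [0,1]: {self.coverage}")


@dataclass
class Params:
    """Scaffolding parameters.

    min_pairs
        Supporting pair number: minimum guide pairs per connection.
    mlc
        Minimal length coverage: a realignment covering at least this
        fraction of its query counts as an ambiguous multi-contig hit.
    mil
        Maximal intron length (bp): connections whose minimal inserted
        size is not smaller than this are rejected.
    default_gap
        Gap size (bp) used when the minimal inserted size already exceeds
        the estimated median intron.
    """

    min_pairs: int = 2
    mlc: float = 0.9
    mil: int = 100_000
    default_gap: int = 100

    def __post_init__(self):
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")
        if not (0.0 < self.mlc <= 1.0):
            raise ValueError("mlc must be in (0, 1]")
        if self.mil <= 0:
            raise ValueError("mil must be positive")
        if self.default_gap <= 0:
            raise ValueError("default_gap must be positive")


# ---------------------------------------------------------------------------
# FASTA


def read_contigs(path: str | Path) -> ContigSet:
    """Read contigs from a FASTA file into a :class:`ContigSet`.

    Duplicate ids and empty sequences are fatal; an empty file yields an
    empty set.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate id: {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for contig {rec.id!r}")
        seqs[rec.id] = seq
    return ContigSet(seqs)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write ``(name, sequence)`` records as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM

#: reference-consuming CIGAR operation codes (M, D, N, =, X)
_REF_OPS = {0, 2, 3, 7, 8}
#: query-consuming operations that are aligned (M, I is consumed but not
#: aligned to the reference; we count M/=/X as aligned query bases)
_ALN_QUERY_OPS = {0, 7, 8}


def cigar_reference_span(cigartuples: list[tuple[int, int]]) -> int:
    """Reference span of a CIGAR: sum of M/D/N/=/X operation lengths."""
    return sum(ln for op, ln in cigartuples if op in _REF_OPS)


def _record_multiplicity(rec: pysam.AlignedSegment, n_records: int, rule: str, mapq_threshold: int) -> bool:
    """Decide uniqueness of a mate's placement under the configured rule."""
    if rule == "mapq":
        return rec.mapping_quality >= mapq_threshold
    if rule == "tag":
        if rec.has_tag("NH"):
            return rec.get_tag("NH") == 1
        # fall back to record counting when the mapper wrote no hit-count tag
        return n_records == 1
    if rule == "single-record":
        return n_records == 1
    raise ValueError(f"unknown uniqueness_rule {rule!r}")


def read_sam_pairs(
    path: str | Path,
    contigs: ContigSet,
    uniqueness_rule: str = "tag",
    mapq_threshold: int = 30,
) -> dict[str, dict[int, list[AlignmentRecord]]]:
    """Read paired-end SAM alignments grouped by read id and mate.

    Primary mapped records become :class:`AlignmentRecord`; secondary and
    supplementary records contribute only to the multiplicity count used by
    the "single-record" uniqueness rule (and the "tag" fallback).  SAM
    1-based POS becomes a 0-based start; the end is the CIGAR reference
    span, so spliced alignments (``N``) keep their full footprint.

    uniqueness_rule
        "tag": an ``NH`` hit-count tag of 1 (falling back to record
        counting when absent); "mapq": MAPQ >= *mapq_threshold*;
        "single-record": exactly one record for the mate.
    """
    pairs: dict[str, dict[int, list[pysam.AlignedSegment]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in contigs:
                raise FormatError(f"SAM reference {name!r} absent from contig set")
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in contigs:
                raise FormatError(f"SAM reference {rec.reference_name!r} absent from contig set")
            if not rec.is_paired:
                raise FormatError(f"unpaired record for read {rec.query_name!r}")
            mate = 1 if rec.is_read1 else 2
            pairs.setdefault(rec.query_name, {}).setdefault(mate, []).append(rec)

    out: dict[str, dict[int, list[AlignmentRecord]]] = {}
    for read_id, mates in pairs.items():
        conv: dict[int, list[AlignmentRecord]] = {}
        for mate, recs in mates.items():
            n_records = len(recs)
            primaries = [r for r in recs if not (r.is_secondary or r.is_supplementary)]
            records = []
            for r in primaries:
                span = cigar_reference_span(r.cigartuples or [])
                if span <= 0:
                    raise FormatError(f"record for {read_id!r} has empty reference span")
                qlen = r.infer_read_length() or (r.query_length or 0)
                aligned = sum(ln for op, ln in (r.cigartuples or []) if op in _ALN_QUERY_OPS)
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        mate=mate,
                        contig_id=r.reference_name,
                        strand="-" if r.is_reverse else "+",
                        start=r.reference_start,
                        end=r.reference_start + span,
                        aligned_query_bases=aligned,
                        query_length=max(qlen, aligned),
                        is_unique=_record_multiplicity(r, n_records, uniqueness_rule, mapq_threshold),
                    )
                )
            # a mate with several primary placements is never unique
            if len(records) > 1:
                records = [
                    AlignmentRecord(
                        read_id=r.read_id, mate=r.mate, contig_id=r.contig_id,
                        strand=r.strand, start=r.start, end=r.end,
                        aligned_query_bases=r.aligned_query_bases,
                        query_length=r.query_length, is_unique=False,
                    )
                    for r in records
                ]
            conv[mate] = records
        out[read_id] = conv
    return out


# ---------------------------------------------------------------------------
# PSL

#: default convention for carrying the mate index in a PSL query name
DEFAULT_MATE_REGEX = r"[/_]([12])$"


def read_psl(path: str | Path, mate_regex: str = DEFAULT_MATE_REGEX) -> list[RealignmentRecord]:
    """Read a 21-column PSL file into realignment records.

    Coverage is ``(matches + repMatches + misMatches) / qSize`` clamped to
    ``[0, 1]``.  PSL coordinates are already 0-based half-open and are kept
    unchanged.  The mate index is parsed from the query-name suffix
    (``/1``/``/2`` or ``_1``/``_2`` by default); records whose names carry
    no mate suffix are fatal, since a pair-aware filter cannot use them.
    """
    pattern = re.compile(mate_regex)
    records: list[RealignmentRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # standard 5-line header
    for lineno, line in enumerate(lines[start:], start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise FormatError(f"line {lineno}: expected 21 PSL columns, got {len(fields)}")
        try:
            matches = int(fields[0])
            mismatches = int(fields[1])
            rep_matches = int(fields[2])
            strand = fields[8]
            q_name = fields[9]
            q_size = int(fields[10])
            t_name = fields[13]
            t_start = int(fields[15])
            t_end = int(fields[16])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed PSL field: {exc}") from exc
        m = pattern.search(q_name)
        if m is None:
            raise FormatError(f"line {lineno}: query name {q_name!r} carries no mate suffix")
        mate = int(m.group(1))
        read_id = q_name[: m.start()]
        if q_size <= 0:
            raise FormatError(f"line {lineno}: non-positive qSize")
        coverage = min(1.0, max(0.0, (matches + rep_matches + mismatches) / q_size))
        records.append(
            RealignmentRecord(
                read_id=read_id,
                mate=mate,
                contig_id=t_name,
                coverage=coverage,
                strand=strand[0] if strand else "+",
                start=t_start,
                end=t_end,
            )
        )
    return records


# ---------------------------------------------------------------------------
# AGP v2.1


@dataclass
class AgpRow:
    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # "W" or "N"
    # W rows
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N rows
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "paired-ends"


def write_agp(path: str | Path, rows: Iterable[AgpRow]) -> None:
    """Write AGP v2.1 rows; gaps use N/scaffold/yes/paired-ends."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "W":
                cols = [
                    r.object, r.object_beg, r.object_end, r.part_number, "W",
                    r.component_id, r.component_beg, r.component_end, r.orientation,
                ]
            elif r.component_type == "N":
                cols = [
                    r.object, r.object_beg, r.object_end, r.part_number, "N",
                    r.gap_length, r.gap_type, r.linkage, r.evidence,
                ]
            else:
                raise FormatError(f"unsupported component type {r.component_type!r}")
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"line {lineno}: expected 9 AGP columns, got {len(f)}")
            if f[4] == "W":
                rows.append(
                    AgpRow(
                        object=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="W", component_id=f[5],
                        component_beg=int(f[6]), component_end=int(f[7]), orientation=f[8],
                    )
                )
            elif f[4] in ("N", "U"):
                rows.append(
                    AgpRow(
                        object=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="N", gap_length=int(f[5]),
                        gap_type=f[6], linkage=f[7], evidence=f[8],
                    )
                )
            else:
                raise FormatError(f"line {lineno}: unsupported component type {f[4]!r}")
    return rows


def reconstruct_from_agp(rows: Iterable[AgpRow], contigs: ContigSet) -> dict[str, str]:
    """Rebuild scaffold sequences from AGP rows plus the contig set.

    Used for the round-trip guarantee: the rebuilt sequences must be
    byte-identical to the emitted scaffold FASTA.
    """
    out: dict[str, str] = {}
    for r in rows:
        parts = out.setdefault(r.object, "")
        if r.component_type == "W":
            if r.component_id not in contigs:
                raise FormatError(f"AGP references unknown contig {r.component_id!r}")
            seq = contigs.sequence(r.component_id)[r.component_beg - 1 : r.component_end]
            if r.orientation == "-":
                seq = revcomp(seq)
            out[r.object] = parts + seq
        else:
            out[r.object] = parts + "N" * r.gap_length
    return out


# ---------------------------------------------------------------------------
# connection TSV

_CONN_HEADER = ["donor", "donor_orient", "acceptor", "acceptor_orient", "weight", "min_insert", "gap"]


def write_connections_tsv(path: str | Path, connections, gaps: Mapping | None = None) -> None:
    """Write aggregated connections as a TSV table.

    *connections* is an iterable of objects with donor / donor_orient /
    acceptor / acceptor_orient / weight / min_insert attributes; *gaps*
    optionally maps a connection's canonical key to the emitted gap size.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_CONN_HEADER) + "\n")
        for c in connections:
            gap = "" if gaps is None else gaps.get(c.key(), "")
            fh.write(
                "\t".join(
                    str(x)
                    for x in [c.donor, c.donor_orient, c.acceptor, c.acceptor_orient, c.weight, c.min_insert, gap]
                )
                + "\n"
            )
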
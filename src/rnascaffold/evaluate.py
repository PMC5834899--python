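"""Accuracy evaluation against a truth placement of contigs.

Following the GAGE-style assembly evaluation, each predicted junction is
compared with the known placement of its two contigs on the reference and
tallied into one of six classes:

* ``CONSISTENCY`` — same order and orientation as the reference, contigs
  adjacent on their reference unit;
* ``CORRECTABLE_RELOCATION`` — order and orientation agree but intervening
  reference sequence shorter than MIL was skipped;
* ``INVERSION`` — relative orientation opposite to the reference;
* ``ERRONEOUS_RELOCATION`` — order contradicts the reference, or the
  skipped distance is at least MIL;
* ``TRANSLOCATION`` — contigs from two different reference chromosomes;
* ``UNKNOWN`` — either contig placed on an unordered reference scaffold,
  where correctness cannot be assessed.

Classes (i) and (ii) count as correct; accuracy is correct / total.  N50
and the corrected N50 (after splitting scaffolds at every erroneous
junction) measure contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph import Connection, ScaffoldPath, flip

__all__ = [
    "TruthPlacement",
    "JunctionClass",
    "ERROR_CLASSES",
    "read_truth_tsv",
    "write_truth_tsv",
    "classify",
    "classify_paths",
    "accuracy",
    "n50",
    "corrected_n50",
    "evaluate_assembly",
]


@dataclass(frozen=True)
class TruthPlacement:
    """Where one contig truly lies on the reference.

    ``rank`` is the contig's order along its reference unit in coordinate
    order; spans of placements on one unit are disjoint.
    """

    contig_id: str
    unit_id: str
    unit_kind: str  # "chromosome" or "scaffold"
    start: int  # 0-based half-open on the unit
    end: int
    strand: str
    rank: int


class JunctionClass(Enum):
    CONSISTENCY = "consistency"
    CORRECTABLE_RELOCATION = "correctable_relocation"
    INVERSION = "inversion"
    ERRONEOUS_RELOCATION = "erroneous_relocation"
    TRANSLOCATION = "translocation"
    UNKNOWN = "unknown"


#: classes at which scaffolds are split for the corrected N50
ERROR_CLASSES = frozenset(
    {JunctionClass.INVERSION, JunctionClass.ERRONEOUS_RELOCATION, JunctionClass.TRANSLOCATION}
)

_TRUTH_COLUMNS = ["contig_id", "unit_id", "unit_kind", "start", "end", "strand", "rank"]


def read_truth_tsv(path: str | Path) -> dict[str, TruthPlacement]:
    """Read truth placements from TSV (0-based half-open coordinates).

    The ``rank`` column is optional; absent ranks are recomputed from
    coordinate order within each unit.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRUTH_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    if "rank" not in df.columns:
        df = df.sort_values(["unit_id", "start"])
        df["rank"] = df.groupby("unit_id").cumcount()
    out: dict[str, TruthPlacement] = {}
    for row in df.itertuples(index=False):
        if row.contig_id in out:
            raise ValueError(f"duplicate truth placement for {row.contig_id!r}")
        out[row.contig_id] = TruthPlacement(
            contig_id=str(row.contig_id), unit_id=str(row.unit_id), unit_kind=str(row.unit_kind),
            start=int(row.start), end=int(row.end), strand=str(row.strand), rank=int(row.rank),
        )
    return out


def write_truth_tsv(path: str | Path, placements: Iterable[TruthPlacement]) -> None:
    df = pd.DataFrame([p.__dict__ for p in placements], columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def classify(conn: Connection, truth: Mapping[str, TruthPlacement], mil: int) -> JunctionClass:
    """Classify one predicted junction against the truth placements."""
    try:
        pd_, pa = truth[conn.donor], truth[conn.acceptor]
    except KeyError as exc:
        raise KeyError(f"no truth placement for contig {exc.args[0]!r}") from exc
    if pd_.unit_kind == "scaffold" or pa.unit_kind == "scaffold":
        return JunctionClass.UNKNOWN
    if pd_.unit_id != pa.unit_id:
        return JunctionClass.TRANSLOCATION

    predicted_same = conn.donor_orient == conn.acceptor_orient
    truth_same = pd_.strand == pa.strand
    if predicted_same != truth_same:
        return JunctionClass.INVERSION

    # the join reads the reference rightward at the donor iff the donor is
    # used in its reference orientation; the acceptor must then lie right
    donor_right_of = conn.donor_orient != pd_.strand
    donor_is_left = pd_.start < pa.start
    ordered_as_predicted = donor_is_left != donor_right_of
    if not ordered_as_predicted:
        return JunctionClass.ERRONEOUS_RELOCATION

    left, right = (pd_, pa) if donor_is_left else (pa, pd_)
    distance = right.start - left.end  # facing-edge gap on the reference
    if abs(pd_.rank - pa.rank) == 1:
        return JunctionClass.CONSISTENCY
    if distance < mil:
        return JunctionClass.CORRECTABLE_RELOCATION
    return JunctionClass.ERRONEOUS_RELOCATION


def classify_paths(
    paths: Sequence[ScaffoldPath], truth: Mapping[str, TruthPlacement], mil: int
) -> list[list[JunctionClass]]:
    """Per-scaffold, per-junction classes, in path order.

    Junctions are classified in the direction the path is written; the
    classification is invariant under mirroring, so this matches
    classifying each junction's canonical connection.
    """
    classes: list[list[JunctionClass]] = []
    for path in paths:
        row = []
        for i, conn in enumerate(path.junctions):
            (d, do), (a, ao) = path.contigs[i], path.contigs[i + 1]
            oriented = Connection(donor=d, donor_orient=do, acceptor=a, acceptor_orient=ao,
                                  weight=conn.weight, min_insert=conn.min_insert)
            row.append(classify(oriented, truth, mil))
        classes.append(row)
    return classes


def accuracy(classes: Iterable[JunctionClass], include_unknown: bool = True) -> float:
    """Fraction of junctions judged correct (consistency + correctable).

    ``UNKNOWN`` junctions stay in the denominator by default — they are
    not demonstrably correct; ``include_unknown=False`` excludes them.
    """
    classes = list(classes)
    if not include_unknown:
        classes = [c for c in classes if c is not JunctionClass.UNKNOWN]
    if not classes:
        raise ValueError("no junctions to evaluate")
    correct = sum(
        c in (JunctionClass.CONSISTENCY, JunctionClass.CORRECTABLE_RELOCATION) for c in classes
    )
    return correct / len(classes)


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold half the bases."""
    if not lengths:
        raise ValueError("n50 of empty length set")
    if any(x <= 0 for x in lengths):
        raise ValueError("n50 requires positive lengths")
    half = sum(lengths) / 2
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def corrected_n50(
    piece_layouts: Sequence[tuple[Sequence[int], Sequence[int]]],
    classes: Sequence[Sequence[JunctionClass]],
) -> int:
    """N50 after splitting scaffolds at every erroneous junction.

    *piece_layouts* gives, per scaffold, its contig lengths and junction
    gap lengths; *classes* the per-junction classes.  At an erroneous
    junction the gap is removed and both flanks are retained.
    """
    if len(piece_layouts) != len(classes):
        raise ValueError("layout/class scaffold counts differ")
    pieces: list[int] = []
    for (contig_lengths, gaps), cls in zip(piece_layouts, classes):
        if len(gaps) != len(contig_lengths) - 1 or len(cls) != len(gaps):
            raise ValueError("junction/class counts do not match contig count")
        current = contig_lengths[0]
        for i, c in enumerate(cls):
            if c in ERROR_CLASSES:
                pieces.append(current)
                current = contig_lengths[i + 1]
            else:
                current += gaps[i] + contig_lengths[i + 1]
        pieces.append(current)
    return n50(pieces)


def evaluate_assembly(
    paths: Sequence[ScaffoldPath],
    gaps: Sequence[Sequence[int]],
    contig_lengths: Mapping[str, int],
    truth: Mapping[str, TruthPlacement],
    mil: int,
    include_unknown: bool = True,
) -> dict:
    """Full evaluation summary: class counts, accuracy, N50, corrected N50."""
    classes = classify_paths(paths, truth, mil)
    flat = [c for row in classes for c in row]
    layouts = [
        ([contig_lengths[cid] for cid in p.ids], list(g)) for p, g in zip(paths, gaps)
    ]
    scaffold_lengths = [sum(cl) + sum(g) for cl, g in layouts]
    summary = {
        "n_junctions": len(flat),
        "class_counts": {c.value: sum(x is c for x in flat) for c in JunctionClass},
        "accuracy": accuracy(flat, include_unknown) if flat else None,
        "n50": n50(scaffold_lengths),
        "corrected_n50": corrected_n50(layouts, classes),
        "classes": classes,
    }
    return summary
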
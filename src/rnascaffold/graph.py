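"""Contig connection graph: orient guide pairs, filter, optimise, link.

Each guide pair is turned into a directed, oriented donor→acceptor
connection (mate 1's contig is the donor; an FR library geometry sets the
orientations).  Connections whose minimal inserted size is not smaller
than the maximal intron length (MIL) are rejected as implausible introns.
Identical oriented joins are merged, their supporting-pair count becoming
the connection weight.  Per contig end, only a unique maximal-weight
connection survives (ties are discarded wholesale as repeat/misalignment
signatures), after which the surviving connections necessarily form simple
paths — the scaffolds — once any cycles are broken at their weakest link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .formats import ContigSet
from .guide_filter import GuidePair

__all__ = [
    "Connection",
    "ScaffoldPath",
    "flip",
    "make_connection",
    "min_insert_size",
    "filter_by_mil",
    "aggregate",
    "select_optimal",
    "build_paths",
    "connection_ends",
]

_FLIP = {"+": "-", "-": "+"}


def flip(orient: str) -> str:
    return _FLIP[orient]


@dataclass(frozen=True)
class Connection:
    """An oriented, weighted contig join.

    The donor in orientation ``donor_orient`` is followed by the acceptor
    in orientation ``acceptor_orient`` (``-`` means reverse complement).
    A physical join has two equivalent directed readings; connections are
    stored canonically with the lexicographically smaller contig id as
    donor, so mirrors compare equal.
    """

    donor: str
    donor_orient: str
    acceptor: str
    acceptor_orient: str
    weight: int = 1
    min_insert: int = 0
    supporting_pairs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("connection must join two distinct contigs")
        if self.min_insert < 0:
            raise ValueError("min_insert must be >= 0")

    def key(self) -> tuple[str, str, str, str]:
        return (self.donor, self.donor_orient, self.acceptor, self.acceptor_orient)

    def mirror(self) -> "Connection":
        """The reverse-complement reading of the same physical join."""
        return replace(
            self,
            donor=self.acceptor,
            donor_orient=flip(self.acceptor_orient),
            acceptor=self.donor,
            acceptor_orient=flip(self.donor_orient),
        )

    def canonical(self) -> "Connection":
        return self if self.donor < self.acceptor else self.mirror()


@dataclass
class ScaffoldPath:
    """An ordered chain of oriented contigs with its junction connections.

    ``junctions[i]`` joins ``contigs[i]`` to ``contigs[i+1]``, so there is
    always one junction fewer than there are contigs.
    """

    contigs: list[tuple[str, str]]
    junctions: list[Connection] = field(default_factory=list)

    def __post_init__(self):
        if len(self.junctions) != len(self.contigs) - 1:
            raise ValueError("junction count must be contig count - 1")

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def reverse(self) -> "ScaffoldPath":
        return ScaffoldPath(
            contigs=[(cid, flip(o)) for cid, o in reversed(self.contigs)],
            junctions=list(reversed(self.junctions)),
        )


def min_insert_size(
    donor_length: int,
    donor_orient: str,
    a_start: int,
    a_end: int,
    acceptor_length: int,
    acceptor_orient: str,
    b_start: int,
    b_end: int,
) -> int:
    """Minimal size of the DNA inserted between the two mate alignments.

    With the donor flank being the sequence past alignment *a* toward the
    join and the acceptor flank the sequence before alignment *b*, the
    minimal inserted size is their sum; in the ++ case this is literally
    ``Length(A) - end(a) + start(b)`` under 0-based half-open coordinates.
    """
    flank_a = donor_length - a_end if donor_orient == "+" else a_start
    flank_b = b_start if acceptor_orient == "+" else acceptor_length - b_end
    return flank_a + flank_b


def make_connection(guide: GuidePair, contigs: ContigSet) -> Connection:
    """Orient one guide pair into a weight-1 canonical connection.

    Mate 1's contig becomes the donor with the mate's strand as its
    orientation; mate 2 reads the fragment's reverse complement in an FR
    library, so the acceptor orientation is the opposite of mate 2's
    strand.
    """
    r1, r2 = guide.rec1, guide.rec2
    donor_orient = r1.strand
    acceptor_orient = flip(r2.strand)
    mi = min_insert_size(
        contigs.length(r1.contig_id), donor_orient, r1.start, r1.end,
        contigs.length(r2.contig_id), acceptor_orient, r2.start, r2.end,
    )
    return Connection(
        donor=r1.contig_id,
        donor_orient=donor_orient,
        acceptor=r2.contig_id,
        acceptor_orient=acceptor_orient,
        weight=1,
        min_insert=mi,
        supporting_pairs=(guide.read_id,),
    ).canonical()


def filter_by_mil(connections: Iterable[Connection], mil: int) -> list[Connection]:
    """Keep connections whose minimal inserted size is strictly below MIL."""
    return [c for c in connections if c.min_insert < mil]


def aggregate(connections: Iterable[Connection], min_pairs: int = 1) -> list[Connection]:
    """Merge identical oriented joins and drop weakly supported ones.

    Weight is the number of supporting pairs; the merged minimal inserted
    size is the minimum over members (the most conservative estimate of
    the intervening sequence).
    """
    grouped: dict[tuple, list[Connection]] = {}
    for c in connections:
        c = c.canonical()
        grouped.setdefault(c.key(), []).append(c)
    merged: list[Connection] = []
    for key in sorted(grouped):
        members = grouped[key]
        pairs: tuple[str, ...] = sum((m.supporting_pairs for m in members), ())
        weight = sum(m.weight for m in members)
        if weight < min_pairs:
            continue
        merged.append(
            Connection(
                donor=key[0], donor_orient=key[1], acceptor=key[2], acceptor_orient=key[3],
                weight=weight,
                min_insert=min(m.min_insert for m in members),
                supporting_pairs=pairs,
            )
        )
    return merged


def connection_ends(conn: Connection) -> tuple[tuple[str, str], tuple[str, str]]:
    """The two physical contig ends a connection occupies.

    A contig's "tail" is its right end in + orientation, "head" its left
    end.  The join leaves the donor through its oriented tail and enters
    the acceptor through its oriented head; both are invariant under
    mirroring.
    """
    donor_end = (conn.donor, "tail" if conn.donor_orient == "+" else "head")
    acceptor_end = (conn.acceptor, "head" if conn.acceptor_orient == "+" else "tail")
    return donor_end, acceptor_end


def select_optimal(connections: Sequence[Connection]) -> list[Connection]:
    """Per contig end, keep only the unique maximal-weight connection.

    Among all connections touching one contig end, the single heaviest is
    selected; if two or more share the maximal weight, every connection at
    that end is discarded (the tie is read as a repeat or misalignment
    signature).  A connection survives only if selected at both its ends.
    """
    at_end: dict[tuple[str, str], list[Connection]] = {}
    for c in connections:
        for end in connection_ends(c):
            at_end.setdefault(end, []).append(c)

    selected: dict[tuple[str, str], Connection | None] = {}
    for end, conns in at_end.items():
        best = max(c.weight for c in conns)
        winners = [c for c in conns if c.weight == best]
        selected[end] = winners[0] if len(winners) == 1 else None

    survivors = []
    for c in connections:
        d_end, a_end = connection_ends(c)
        if selected[d_end] is c and selected[a_end] is c:
            survivors.append(c)
    return survivors


def build_paths(survivors: Sequence[Connection], all_contigs: Iterable[str]) -> list[ScaffoldPath]:
    """Link optimal connections into scaffold paths.

    After per-end optimisation every contig end carries at most one
    connection, so connected components are simple paths or cycles; cycles
    are broken by removing their minimum-weight connection (ties broken on
    the lexicographically smallest canonical key).  Contigs with no
    surviving connection come out as singleton paths in + orientation.
    """
    adjacency: dict[str, dict[str, Connection]] = {}
    for c in survivors:
        for cid, side in connection_ends(c):
            sides = adjacency.setdefault(cid, {})
            if side in sides:
                raise RuntimeError(f"contig end ({cid},{side}) has degree > 1")
            sides[side] = c

    g = nx.MultiGraph()
    g.add_nodes_from(adjacency)
    for i, c in enumerate(survivors):
        g.add_edge(c.donor, c.acceptor, key=i, conn=c)

    paths: list[ScaffoldPath] = []
    connected: set[str] = set()
    for comp in nx.connected_components(g):
        comp_edges = {
            data["conn"] for _, _, data in g.edges(comp, data=True)
        }
        degrees = {n: g.degree(n) for n in comp}
        if comp_edges and all(d == 2 for d in degrees.values()):
            # cycle: drop the weakest link
            drop = min(comp_edges, key=lambda c: (c.weight, c.key()))
            for cid, side in connection_ends(drop):
                del adjacency[cid][side]
            comp_edges.discard(drop)
        # find a terminus: a contig using at most one of its ends
        termini = sorted(n for n in comp if len(adjacency.get(n, {})) <= 1)
        if not comp_edges:
            for n in sorted(comp):
                paths.append(ScaffoldPath(contigs=[(n, "+")]))
                connected.add(n)
            continue
        start = termini[0]
        (start_side,) = adjacency[start].keys()
        orient = "+" if start_side == "tail" else "-"
        chain: list[tuple[str, str]] = [(start, orient)]
        junctions: list[Connection] = []
        cur, cur_orient, entered_by = start, orient, None
        while True:
            forward = "tail" if cur_orient == "+" else "head"
            conn = adjacency.get(cur, {}).get(forward)
            if conn is None or conn is entered_by:
                break
            if conn.donor == cur:
                nxt, nxt_orient = conn.acceptor, conn.acceptor_orient
            else:
                nxt, nxt_orient = conn.donor, flip(conn.donor_orient)
            junctions.append(conn)
            chain.append((nxt, nxt_orient))
            cur, cur_orient, entered_by = nxt, nxt_orient, conn
        path = ScaffoldPath(contigs=chain, junctions=junctions)
        if path.contigs[0][0] > path.contigs[-1][0]:
            path = path.reverse()
        paths.append(path)
        connected.update(path.ids)

    for cid in sorted(set(all_contigs) - connected):
        paths.append(ScaffoldPath(contigs=[(cid, "+")]))
    paths.sort(key=lambda p: p.contigs[0][0])
    return paths
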
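"""Connection graph: orientation geometry, per-end optimisation, path walk."""

import random

import pytest

from rnascaffold.formats import AlignmentRecord, ContigSet
from rnascaffold.graph import (
    Connection,
    aggregate,
    build_paths,
    connection_ends,
    filter_by_mil,
    flip,
    make_connection,
    min_insert_size,
    select_optimal,
)
from rnascaffold.guide_filter import GuidePair


def conn(d, do, a, ao, weight=1, mi=0, pairs=None):
    return Connection(donor=d, donor_orient=do, acceptor=a, acceptor_orient=ao,
                      weight=weight, min_insert=mi,
                      supporting_pairs=tuple(pairs or [f"p{random.random()}"]))


# ------------------------------------------------------------ minimal insert


def test_min_insert_plus_plus_is_the_flank_sum():
    assert min_insert_size(1000, "+", 850, 900, 800, "+", 50, 120) == 150


def test_min_insert_zero_flanks():
    assert min_insert_size(1000, "+", 900, 1000, 800, "+", 0, 100) == 0


def test_min_insert_minus_minus():
    assert min_insert_size(1000, "-", 30, 80, 500, "-", 400, 480) == 50


def oracle_min_insert(dl, do, a0, a1, al, ao, b0, b1):
    """Materialise both oriented contigs as position lists, concatenate,
    and measure the distance between the two mapped footprints."""
    donor = [("A", p) for p in range(dl)]
    acceptor = [("B", p) for p in range(al)]
    if do == "-":
        donor.reverse()
    if ao == "-":
        acceptor.reverse()
    joined = donor + acceptor
    a_idx = [i for i, (c, p) in enumerate(joined) if c == "A" and a0 <= p < a1]
    b_idx = [i for i, (c, p) in enumerate(joined) if c == "B" and b0 <= p < b1]
    return min(b_idx) - (max(a_idx) + 1)


def test_min_insert_matches_concatenation_oracle_on_random_configs():
    rng = random.Random(42)
    for _ in range(1000):
        dl, al = rng.randint(2, 300), rng.randint(2, 300)
        a0 = rng.randrange(dl - 1)
        a1 = rng.randint(a0 + 1, dl)
        b0 = rng.randrange(al - 1)
        b1 = rng.randint(b0 + 1, al)
        do, ao = rng.choice("+-"), rng.choice("+-")
        assert min_insert_size(dl, do, a0, a1, al, ao, b0, b1) == oracle_min_insert(
            dl, do, a0, a1, al, ao, b0, b1
        )


# ----------------------------------------------------------- FR orientation


@pytest.fixture
def ab_contigs():
    return ContigSet({"A": "A" * 1000, "B": "C" * 800})


def guide(s1, s2, a=(850, 900), b=(50, 120)):
    r1 = AlignmentRecord(read_id="g", mate=1, contig_id="A", strand=s1, start=a[0], end=a[1],
                         aligned_query_bases=50, query_length=100, is_unique=True)
    r2 = AlignmentRecord(read_id="g", mate=2, contig_id="B", strand=s2, start=b[0], end=b[1],
                         aligned_query_bases=70, query_length=100, is_unique=True)
    return GuidePair(read_id="g", rec1=r1, rec2=r2)


def test_fr_geometry_plus_minus_gives_forward_join(ab_contigs):
    c = make_connection(guide("+", "-"), ab_contigs)
    assert c.key() == ("A", "+", "B", "+")
    assert c.min_insert == 150


def test_fr_geometry_minus_plus_flips_both(ab_contigs):
    c = make_connection(guide("-", "+"), ab_contigs)
    # A- -> B- reads canonically as A- -> B- (donor id already smaller)
    assert c.key() == ("A", "-", "B", "-")


def test_mirror_readings_share_canonical_form():
    c = conn("A", "+", "B", "+")
    m = conn("B", "-", "A", "-")
    assert c.canonical().key() == m.canonical().key()
    assert connection_ends(c.canonical()) == tuple(reversed(connection_ends(m)))


# ------------------------------------------------------------------- filters


@pytest.mark.parametrize("mi,mil,kept", [(150, 100_000, True), (200_000, 100_000, False), (100_000, 100_000, False)])
def test_mil_filter_is_strict(mi, mil, kept):
    out = filter_by_mil([conn("A", "+", "B", "+", mi=mi)], mil)
    assert bool(out) is kept


def test_aggregate_merges_identical_joins():
    cs = [conn("A", "+", "B", "+", mi=m, pairs=[f"p{i}"]) for i, m in enumerate((120, 80, 200))]
    (merged,) = aggregate(cs, min_pairs=1)
    assert merged.weight == 3
    assert merged.min_insert == 80
    assert len(merged.supporting_pairs) == 3


def test_aggregate_merges_mirror_readings():
    cs = [conn("A", "+", "B", "+", pairs=["p1"]), conn("B", "-", "A", "-", pairs=["p2"])]
    (merged,) = aggregate(cs, min_pairs=1)
    assert merged.weight == 2


def test_aggregate_drops_below_min_pairs():
    assert aggregate([conn("A", "+", "B", "+")], min_pairs=2) == []


# ------------------------------------------------------------- optimisation


def test_heaviest_connection_wins_at_an_end():
    c5 = conn("A", "+", "B", "+", weight=5)
    c3 = conn("A", "+", "C", "+", weight=3)  # same donor end of A
    surv = select_optimal([c5, c3])
    assert surv == [c5]


def test_tied_end_discards_all_connections_there():
    c1 = conn("A", "+", "B", "+", weight=4)
    c2 = conn("A", "+", "C", "+", weight=4)
    assert select_optimal([c1, c2]) == []


def test_winner_at_one_end_can_lose_at_the_other():
    # A+->B+ wins its donor end but B's head is dominated by C+->B+
    ab = conn("A", "+", "B", "+", weight=3)
    cb = conn("C", "+", "B", "+", weight=7)
    surv = select_optimal([ab, cb])
    assert surv == [cb]


def oracle_select(conns):
    """Exhaustive per-end check: survive iff strictly heavier than every
    other connection at both occupied ends."""
    out = []
    for c in conns:
        ok = True
        for end in connection_ends(c):
            for other in conns:
                if other is c:
                    continue
                if end in connection_ends(other) and other.weight >= c.weight:
                    ok = False
        if ok:
            out.append(c)
    return out


def random_instance(rng, n_contigs, n_conns):
    names = [f"c{i}" for i in range(n_contigs)]
    conns = []
    seen = set()
    for _ in range(n_conns):
        d, a = rng.sample(names, 2)
        c = conn(d, rng.choice("+-"), a, rng.choice("+-"), weight=rng.randint(1, 6)).canonical()
        if c.key() in seen:
            continue
        seen.add(c.key())
        conns.append(c)
    return conns


def test_select_optimal_matches_exhaustive_enumeration():
    rng = random.Random(7)
    for _ in range(200):
        conns = random_instance(rng, rng.randint(3, 20), rng.randint(1, 30))
        assert set(map(id, select_optimal(conns))) == set(map(id, oracle_select(conns)))


# ------------------------------------------------------------------ pathing


def test_chain_walks_to_single_path():
    surv = select_optimal([conn("A", "+", "B", "+", weight=2), conn("B", "+", "C", "+", weight=2)])
    (path,) = build_paths(surv, ["A", "B", "C"])
    assert path.contigs == [("A", "+"), ("B", "+"), ("C", "+")]


def test_cycle_broken_at_minimum_weight():
    cs = [
        conn("A", "+", "B", "+", weight=5),
        conn("B", "+", "C", "+", weight=4),
        conn("C", "+", "A", "+", weight=3),
    ]
    surv = select_optimal(cs)
    assert len(surv) == 3  # every end has a unique winner; pure cycle
    (path,) = build_paths(surv, ["A", "B", "C"])
    assert path.contigs == [("A", "+"), ("B", "+"), ("C", "+")]
    assert [j.weight for j in path.junctions] == [5, 4]


def test_unconnected_contig_emitted_as_singleton():
    paths = build_paths([], ["D"])
    assert [p.contigs for p in paths] == [[("D", "+")]]


def test_path_orientation_normalised_by_terminal_ids():
    # walking from Z would be valid; output must start at the smaller id
    surv = select_optimal([conn("Z", "+", "A", "+", weight=2)])
    (path,) = build_paths(surv, ["A", "Z"])
    assert path.contigs[0][0] == "A"
    assert path.contigs == [("A", "-"), ("Z", "-")]


def test_paths_partition_contigs_and_stay_acyclic():
    rng = random.Random(3)
    for _ in range(50):
        names = [f"c{i}" for i in range(rng.randint(4, 20))]
        conns = random_instance(rng, len(names), rng.randint(2, 40))
        surv = select_optimal(aggregate(conns, 1))
        paths = build_paths(surv, names)
        seen = [cid for p in paths for cid in p.ids]
        assert sorted(seen) == sorted(names)  # exactly once each
        for p in paths:
            assert len(p.junctions) == len(p.contigs) - 1
            assert len(set(p.ids)) == len(p.ids)  # no cycles within a path


def test_reverse_complement_invariance_of_physical_joins(small_run):
    """Flipping every contig (and remapping alignments) must leave the set
    of physical joins unchanged up to the mirror reading."""
    sim, result = small_run
    contigs = result.contigs
    flipped_conns = []
    for g in result.guides:
        recs = []
        for r in (g.rec1, g.rec2):
            length = contigs.length(r.contig_id)
            recs.append(
                AlignmentRecord(
                    read_id=r.read_id, mate=r.mate, contig_id=r.contig_id,
                    strand=flip(r.strand), start=length - r.end, end=length - r.start,
                    aligned_query_bases=r.aligned_query_bases,
                    query_length=r.query_length, is_unique=True,
                )
            )
        flipped_conns.append(make_connection(GuidePair(g.read_id, recs[0], recs[1]), contigs))
    # flipping contig sequences flips both orientations of each join
    def unflip(c):
        return Connection(donor=c.donor, donor_orient=flip(c.donor_orient),
                          acceptor=c.acceptor, acceptor_orient=flip(c.acceptor_orient),
                          weight=c.weight, min_insert=c.min_insert).canonical()

    original = {make_connection(g, contigs).key() for g in result.guides}
    assert {unflip(c).key() for c in flipped_conns} == original
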
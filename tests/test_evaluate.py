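"""Junction classification, accuracy, N50 and corrected N50."""

import random

import pytest

from rnascaffold.evaluate import (
    JunctionClass,
    TruthPlacement,
    accuracy,
    classify,
    corrected_n50,
    n50,
)
from rnascaffold.graph import Connection


def t(contig, unit="chr1", kind="chromosome", start=0, end=100, strand="+", rank=0):
    return TruthPlacement(contig_id=contig, unit_id=unit, unit_kind=kind,
                          start=start, end=end, strand=strand, rank=rank)


def c(do, ao, donor="D", acceptor="A"):
    return Connection(donor=donor, donor_orient=do, acceptor=acceptor, acceptor_orient=ao, weight=2)


MIL = 100_000

# twelve hand-constructed cases, two or more per class
CASES = [
    # (i) consistency: rank-adjacent, same order and orientation
    ("++ adjacent forward", c("+", "+"),
     {"D": t("D", start=0, end=100, rank=0), "A": t("A", start=200, end=300, rank=1)},
     JunctionClass.CONSISTENCY),
    ("-- adjacent read right-to-left", c("-", "-"),
     {"D": t("D", start=200, end=300, rank=1), "A": t("A", start=0, end=100, rank=0)},
     JunctionClass.CONSISTENCY),
    # (ii) correctable relocation: ordered, skipped distance < MIL
    ("skip one contig, 50 kb gap", c("+", "+"),
     {"D": t("D", start=0, end=100, rank=0), "A": t("A", start=50_100, end=50_200, rank=2)},
     JunctionClass.CORRECTABLE_RELOCATION),
    ("reverse walk, 99,999 bp gap", c("-", "-"),
     {"D": t("D", start=100_099, end=100_199, rank=3), "A": t("A", start=0, end=100, rank=0)},
     JunctionClass.CORRECTABLE_RELOCATION),
    # (iii) inversion: relative orientation disagrees with the reference
    ("acceptor flipped", c("+", "-"),
     {"D": t("D", start=0, end=100, rank=0), "A": t("A", start=200, end=300, rank=1)},
     JunctionClass.INVERSION),
    ("reference strands differ", c("+", "+"),
     {"D": t("D", start=0, end=100, rank=0), "A": t("A", start=200, end=300, strand="-", rank=1)},
     JunctionClass.INVERSION),
    # (iv) erroneous relocation: too far, or order contradicts
    ("200 kb skipped", c("+", "+"),
     {"D": t("D", start=0, end=100, rank=0), "A": t("A", start=200_100, end=200_200, rank=5)},
     JunctionClass.ERRONEOUS_RELOCATION),
    ("order reversed", c("+", "+"),
     {"D": t("D", start=200, end=300, rank=1), "A": t("A", start=0, end=100, rank=0)},
     JunctionClass.ERRONEOUS_RELOCATION),
    # (v) translocation: two reference chromosomes
    ("chr1 vs chr2", c("+", "+"),
     {"D": t("D"), "A": t("A", unit="chr2")},
     JunctionClass.TRANSLOCATION),
    ("chr2 vs chr3 inverted", c("+", "-"),
     {"D": t("D", unit="chr2"), "A": t("A", unit="chr3")},
     JunctionClass.TRANSLOCATION),
    # (vi) unknown: a reference scaffold is involved
    ("acceptor on scaffold", c("+", "+"),
     {"D": t("D"), "A": t("A", unit="scaf9", kind="scaffold")},
     JunctionClass.UNKNOWN),
    ("donor on scaffold", c("-", "+"),
     {"D": t("D", unit="scaf1", kind="scaffold"), "A": t("A")},
     JunctionClass.UNKNOWN),
]


@pytest.mark.parametrize("label,conn,truth,expected", CASES, ids=[x[0] for x in CASES])
def test_junction_classification_truth_table(label, conn, truth, expected):
    assert classify(conn, truth, MIL) is expected


def test_classification_is_mirror_invariant():
    for label, conn, truth, expected in CASES:
        mirrored = conn.mirror()
        assert classify(mirrored, truth, MIL) is expected, label


def test_missing_truth_placement_is_fatal():
    with pytest.raises(KeyError):
        classify(c("+", "+"), {"D": t("D")}, MIL)


# ---------------------------------------------------------------- accuracy


def test_accuracy_ratio():
    classes = [JunctionClass.CONSISTENCY] * 9 + [JunctionClass.TRANSLOCATION]
    assert accuracy(classes) == pytest.approx(0.9)


def test_accuracy_counts_correctable_as_correct():
    classes = [JunctionClass.CORRECTABLE_RELOCATION, JunctionClass.ERRONEOUS_RELOCATION]
    assert accuracy(classes) == pytest.approx(0.5)


def test_accuracy_all_consistent():
    assert accuracy([JunctionClass.CONSISTENCY] * 4) == 1.0


def test_accuracy_unknown_denominator_modes():
    classes = [JunctionClass.CONSISTENCY, JunctionClass.UNKNOWN]
    assert accuracy(classes) == pytest.approx(0.5)
    assert accuracy(classes, include_unknown=False) == 1.0


def test_accuracy_empty_is_an_error():
    with pytest.raises(ValueError, match="no junctions"):
        accuracy([])


# --------------------------------------------------------------------- N50


@pytest.mark.parametrize("lengths,expected", [([100, 50, 50], 100), ([80, 70, 50], 70), ([42], 42)])
def test_n50_examples(lengths, expected):
    assert n50(lengths) == expected


def oracle_n50(lengths):
    total = sum(lengths)
    return max(L for L in lengths if sum(x for x in lengths if x >= L) >= total / 2)


def test_n50_matches_bruteforce_on_random_multisets():
    rng = random.Random(99)
    for _ in range(1000):
        lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 30))]
        assert n50(lengths) == oracle_n50(lengths)


# ----------------------------------------------------------- corrected N50


def test_corrected_equals_n50_without_errors():
    layouts = [([100, 200, 50], [10, 10])]
    classes = [[JunctionClass.CONSISTENCY, JunctionClass.CORRECTABLE_RELOCATION]]
    assert corrected_n50(layouts, classes) == n50([100 + 10 + 200 + 10 + 50])


def test_corrected_splits_at_error_junction():
    # A(100) -gap- B(100) -gap(7)- C(100), B-C junction is a translocation:
    # pieces are A+gap+B (205) and C (100)
    layouts = [([100, 100, 100], [5, 7])]
    classes = [[JunctionClass.CONSISTENCY, JunctionClass.TRANSLOCATION]]
    assert corrected_n50(layouts, classes) == n50([205, 100])


def test_corrected_never_exceeds_n50():
    rng = random.Random(5)
    all_classes = list(JunctionClass)
    for _ in range(200):
        n_scaf = rng.randint(1, 4)
        layouts, classes = [], []
        for _ in range(n_scaf):
            k = rng.randint(1, 6)
            contig_lengths = [rng.randint(10, 400) for _ in range(k)]
            gaps = [rng.randint(1, 100) for _ in range(k - 1)]
            layouts.append((contig_lengths, gaps))
            classes.append([rng.choice(all_classes) for _ in range(k - 1)])
        whole = [sum(cl) + sum(g) for cl, g in layouts]
        assert corrected_n50(layouts, classes) <= n50(whole)


def test_mismatched_counts_fatal():
    with pytest.raises(ValueError):
        corrected_n50([([100, 100], [5])], [[]])
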
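"""Scaled-down synthetic study harnesses.

These bundle the simulator and the pipeline into the small experiments the
package uses to characterise itself: an end-to-end recovery study on a
densely transcribed genome, a noise trade-off study on a sparsely
transcribed one, a filter-stage parameter sweep, and a sequencing-depth
study.  Each returns plain dictionaries of measured quantities.
"""

from __future__ import annotations

import numpy as np

from . import graph as _graph
from .evaluate import ERROR_CLASSES, evaluate_assembly
from .formats import Params
from .guide_filter import first_round_filter, realign_filter
from .pipeline import ScaffoldResult, scaffold
from .simulate import SimConfig, Simulation, simulate_all

__all__ = [
    "dense_config",
    "sparse_config",
    "run_simulated",
    "recovery_study",
    "noise_study",
    "filter_sweep",
    "depth_study",
]


def dense_config(seed: int, **overrides) -> SimConfig:
    """Densely transcribed study genome: 5 units x 100 kb, 40 genes each,
    199 intronic breaks, 10 error-free pairs per junction.  Nearly every
    contig junction is spanned by a transcript, so near-complete recovery
    is expected."""
    base = dict(
        seed=seed, n_units=5, unit_length=100_000, n_genes_per_unit=40,
        n_contig_breaks=199, break_preference=1.0, pairs_per_junction=10,
    )
    base.update(overrides)
    return SimConfig(**base)


def sparse_config(seed: int, **overrides) -> SimConfig:
    """Sparsely transcribed study genome for the noise trade-off.

    Real genomes offer noise somewhere to attach: most contig ends carry
    no transcript evidence, and informative guide pairs are a small
    minority of all read pairs.  This condition emulates that with fewer
    genes, breaks that often fall outside introns, and a large background
    of ordinary (mostly intra-contig) pairs.
    """
    base = dict(
        seed=seed, n_units=5, unit_length=100_000, n_genes_per_unit=15,
        n_contig_breaks=199, break_preference=0.4, pairs_per_junction=10,
        background_pairs_per_gene=30,
    )
    base.update(overrides)
    return SimConfig(**base)


def _reparse(sim: Simulation):
    """Round the simulation through its own text formats, as a real run
    would consume them."""
    import tempfile
    from pathlib import Path

    from .formats import read_contigs, read_psl, read_sam_pairs

    with tempfile.TemporaryDirectory() as d:
        d = Path(d)
        sim.write_contig_fasta(d / "contigs.fasta")
        sim.write_sam(d / "pairs.sam")
        sim.write_psl(d / "pairs.psl")
        contigs = read_contigs(d / "contigs.fasta")
        pair_stream = read_sam_pairs(d / "pairs.sam", contigs)
        realignments = read_psl(d / "pairs.psl")
    return contigs, pair_stream, realignments


def run_simulated(config: SimConfig, params: Params | None = None) -> tuple[Simulation, ScaffoldResult]:
    """Simulate, write/re-read through the standard formats, scaffold."""
    sim = simulate_all(config)
    contigs, pair_stream, realignments = _reparse(sim)
    result = scaffold(contigs, pair_stream, realignments, params)
    return sim, result


def junction_recovery(sim: Simulation, result: ScaffoldResult) -> tuple[float, int]:
    """(fraction of true junctions present in the output paths, number of
    predicted junctions that are not true adjacencies)."""
    true_j = {frozenset((j.left_contig, j.right_contig)) for j in sim.junctions}
    pred = {
        frozenset((a, b))
        for p in result.paths
        for a, b in zip(p.ids, p.ids[1:])
    }
    return len(pred & true_j) / len(true_j), len(pred - true_j)


def recovery_study(seed: int, params: Params | None = None) -> dict:
    """End-to-end recovery on the dense condition with default parameters."""
    params = params or Params()
    sim, result = run_simulated(dense_config(seed), params)
    summary = evaluate_assembly(
        result.paths, result.assembly.gaps, result.contigs.lengths(), sim.truth, params.mil
    )
    recovery, false_junctions = junction_recovery(sim, result)
    return {
        "n_true_junctions": len(sim.junctions),
        "n_predicted_junctions": summary["n_junctions"],
        "recovery": recovery,
        "false_junctions": false_junctions,
        "accuracy": summary["accuracy"],
        "n50": summary["n50"],
        "corrected_n50": summary["corrected_n50"],
        "n50_before": result.stats["n50_before"],
        "class_counts": summary["class_counts"],
    }


def noise_study(seed: int, noise_fraction: float = 0.05, replicates: int = 3) -> dict:
    """Supporting-pair-number trade-off under mis-mapped read pairs.

    Runs *replicates* independent sparse-condition genomes.  With a
    supporting pair number of 1, spurious weight-1 connections can attach
    to transcript-free contig ends and surface as erroneous junction
    classes; raising it to 2 removes them.
    """
    err1 = 0
    acc1 = []
    acc2 = []
    n1 = n2 = 0
    for r in range(replicates):
        cfg = sparse_config(seed + 1000 * r, noise_fraction=noise_fraction)
        sim, res1 = run_simulated(cfg, Params(min_pairs=1))
        s1 = evaluate_assembly(res1.paths, res1.assembly.gaps, res1.contigs.lengths(), sim.truth, 100_000)
        err1 += sum(s1["class_counts"][c.value] for c in ERROR_CLASSES)
        acc1.append(s1["accuracy"])
        n1 += s1["n_junctions"]
        sim, res2 = run_simulated(cfg, Params(min_pairs=2))
        s2 = evaluate_assembly(res2.paths, res2.assembly.gaps, res2.contigs.lengths(), sim.truth, 100_000)
        acc2.append(s2["accuracy"])
        n2 += s2["n_junctions"]
    return {
        "replicates": replicates,
        "min_pairs1_error_junctions": err1,
        "min_pairs1_accuracy": float(np.mean(acc1)),
        "min_pairs2_accuracy": float(np.mean(acc2)),
        "min_pairs1_junctions": n1,
        "min_pairs2_junctions": n2,
    }


def filter_sweep(
    seed: int,
    min_pairs_values=(1, 2, 3, 4, 5),
    mil_values=(10_000, 50_000, 100_000, 200_000, 500_000),
) -> dict:
    """Pre-optimisation connection counts as the filters tighten.

    On one fixed sparse-condition dataset, counts are non-increasing in
    the supporting pair number and non-decreasing in MIL.
    """
    cfg = sparse_config(seed, noise_fraction=0.05)
    sim = simulate_all(cfg)
    contigs, pair_stream, realignments = _reparse(sim)
    candidates, _ = first_round_filter(pair_stream)
    guides = realign_filter(candidates, realignments, 0.9)
    raw = [_graph.make_connection(g, contigs) for g in guides]

    by_min_pairs = {
        k: len(_graph.aggregate(_graph.filter_by_mil(raw, 100_000), k)) for k in min_pairs_values
    }
    by_mil = {m: len(_graph.aggregate(_graph.filter_by_mil(raw, m), 2)) for m in mil_values}
    return {"connections_by_min_pairs": by_min_pairs, "connections_by_mil": by_mil}


def _genome_coverage(sim: Simulation, pair_ids: set[str]) -> float:
    """Fraction of genome bases covered by the span between the two mate
    alignments of same-unit pairs, computed from the simulator's known
    placements."""
    spans: dict[str, list[tuple[int, int]]] = {u: [] for u in sim.units}
    placements = sim.truth
    for p in sim.pairs:
        if p.read_id not in pair_ids:
            continue
        t1, t2 = placements.get(p.mate1.contig_id), placements.get(p.mate2.contig_id)
        if t1 is None or t2 is None or t1.unit_id != t2.unit_id:
            continue
        g1 = (t1.start + p.mate1.start, t1.start + p.mate1.end)
        g2 = (t2.start + p.mate2.start, t2.start + p.mate2.end)
        spans[t1.unit_id].append((min(g1[0], g2[0]), max(g1[1], g2[1])))
    covered = 0
    for unit, intervals in spans.items():
        intervals.sort()
        last_end = -1
        for s, e in intervals:
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
    total = sum(len(s) for s in sim.units.values())
    return covered / total


def depth_study(seed: int, fractions=(0.25, 0.5, 0.75, 1.0)) -> dict:
    """Sequencing-depth sampling: N50 and genome coverage per subset.

    Pairs are subsampled at each fraction from one sparse-condition
    simulation; the correlation between genome coverage and N50 is
    reported.
    """
    cfg = sparse_config(seed)
    sim = simulate_all(cfg)
    contigs, pair_stream, realignments = _reparse(sim)
    rng = np.random.default_rng(seed)
    read_ids = sorted(pair_stream)
    order = rng.permutation(len(read_ids))
    rows = []
    for frac in fractions:
        keep = {read_ids[i] for i in order[: int(round(frac * len(read_ids)))]}
        sub_stream = {rid: m for rid, m in pair_stream.items() if rid in keep}
        sub_realign = [r for r in realignments if r.read_id in keep]
        result = scaffold(contigs, sub_stream, sub_realign, Params())
        rows.append(
            {
                "fraction": frac,
                "coverage": _genome_coverage(sim, keep),
                "n50": result.stats["n50_after"],
                "n_junctions": result.stats["n_junctions"],
            }
        )
    cov = np.array([r["coverage"] for r in rows])
    n50s = np.array([r["n50"] for r in rows], dtype=float)
    r = float(np.corrcoef(cov, n50s)[0, 1]) if len(rows) > 1 and n50s.std() > 0 else float("nan")
    return {"samples": rows, "coverage_n50_correlation": r}
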
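import logging

import pytest
from hypothesis import settings as _hsettings

from rnascaffold.formats import Params, read_contigs, read_psl, read_sam_pairs
from rnascaffold.pipeline import scaffold
from rnascaffold.simulate import SimConfig, simulate_all

logging.getLogger("rnascaffold").setLevel(logging.ERROR)

_hsettings.register_profile("repro", derandomize=True)
_hsettings.load_profile("repro")


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free simulated genome: 2 units, 40 breaks."""
    config = SimConfig(seed=11, n_units=2, unit_length=60_000, n_genes_per_unit=20, n_contig_breaks=40)
    return simulate_all(config)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """The small simulation scaffolded end-to-end through its text formats."""
    d = tmp_path_factory.mktemp("small_run")
    small_sim.write_contig_fasta(d / "contigs.fasta")
    small_sim.write_sam(d / "pairs.sam")
    small_sim.write_psl(d / "pairs.psl")
    contigs = read_contigs(d / "contigs.fasta")
    pair_stream = read_sam_pairs(d / "pairs.sam", contigs)
    realignments = read_psl(d / "pairs.psl")
    result = scaffold(contigs, pair_stream, realignments, Params())
    return small_sim, result


def write_sam_text(path, contigs, records):
    """Write a minimal SAM file from (qname, flag, rname, pos1, mapq, cigar, tags) tuples."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for cid in contigs.ids:
            fh.write(f"@SQ\tSN:{cid}\tLN:{contigs.length(cid)}\n")
        for qname, flag, rname, pos1, mapq, cigar, *tags in records:
            fields = [qname, str(flag), rname, str(pos1), str(mapq), cigar, "*", "0", "0", "*", "*"] + list(tags)
            fh.write("\t".join(fields) + "\n")
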
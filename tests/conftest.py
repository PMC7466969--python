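import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from hgtcensus.io_formats import CoverageTrack, GeneModel, HitRecord
from hgtcensus.synthetic_data import SimulationConfig, simulate_genome

TOY_GFF3 = """\
##gff-version 3
scaffold_1\ttoy\tgene\t1\t300\t.\t+\t.\tID=gA
scaffold_1\ttoy\tmRNA\t1\t300\t.\t+\t.\tID=gA.t1;Parent=gA
scaffold_1\ttoy\texon\t1\t100\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
scaffold_1\ttoy\texon\t201\t300\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
scaffold_1\ttoy\tCDS\t11\t100\t.\t+\t0\tID=gA.t1.c1;Parent=gA.t1
scaffold_1\ttoy\tCDS\t201\t299\t.\t+\t0\tID=gA.t1.c2;Parent=gA.t1
scaffold_1\ttoy\tgene\t401\t700\t.\t+\t.\tID=gB
scaffold_1\ttoy\tmRNA\t401\t700\t.\t+\t.\tID=gB.t1;Parent=gB
scaffold_1\ttoy\texon\t401\t700\t.\t+\t.\tID=gB.t1.e1;Parent=gB.t1
scaffold_1\ttoy\tCDS\t401\t700\t.\t+\t0\tID=gB.t1.c1;Parent=gB.t1
scaffold_1\ttoy\tmRNA\t401\t700\t.\t+\t.\tID=gB.t2;Parent=gB
scaffold_1\ttoy\texon\t401\t700\t.\t+\t.\tID=gB.t2.e1;Parent=gB.t2
scaffold_1\ttoy\tCDS\t401\t550\t.\t+\t0\tID=gB.t2.c1;Parent=gB.t2
scaffold_2\ttoy\tgene\t1\t450\t.\t-\t.\tID=gC
scaffold_2\ttoy\tmRNA\t1\t450\t.\t-\t.\tID=gC.t1;Parent=gC
scaffold_2\ttoy\texon\t1\t150\t.\t-\t.\tID=gC.t1.e1;Parent=gC.t1
scaffold_2\ttoy\texon\t301\t450\t.\t-\t.\tID=gC.t1.e2;Parent=gC.t1
scaffold_2\ttoy\tCDS\t1\t150\t.\t-\t0\tID=gC.t1.c1;Parent=gC.t1
scaffold_2\ttoy\tCDS\t301\t450\t.\t-\t0\tID=gC.t1.c2;Parent=gC.t1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


def make_gene(gene_id, scaffold="s1", start=0, exons=((0, 300),), strand="+"):
    span = (exons[0][0], exons[-1][1])
    cds_len = sum(e - s for s, e in exons)
    cds_len -= cds_len % 3
    return GeneModel(
        gene_id=gene_id,
        scaffold_id=scaffold,
        strand=strand,
        span=span,
        exons=tuple(exons),
        cds_length=cds_len,
        protein_length=cds_len // 3,
    )


def make_hit(query, kingdom="bacteria", group=None, evalue=1e-50, bitscore=200.0, subject="s"):
    if group is None:
        group = "fungi" if kingdom == "fungi" else "firmicutes"
    return HitRecord(
        query_id=query,
        subject_id=subject,
        evalue=evalue,
        bitscore=bitscore,
        taxonomy_group=group,
        superkingdom=kingdom,
    )


@pytest.fixture(scope="session")
def default_truth():
    """Noise-free default genome: 200 genes, 5% planted, 1 contaminant scaffold."""
    return simulate_genome(SimulationConfig(seed=0))
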
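"""Shared fixtures: tiny hand-written format files and simulated datasets."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from snppanel import sim
from snppanel.containers import MISSING, GenotypeMatrix, MarkerRecord


@pytest.fixture
def tiny_vcf(tmp_path):
    """2 samples x 3 records: plain biallelic, half-missing GT, multiallelic."""
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##contig=<ID=chr1>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
        chr1\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1
        chr1\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.
        chr1\t300\tm3\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/.
        """
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_fasta(tmp_path):
    """One 200 bp contig with a fixed seeded sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    path = tmp_path / "ref.fa"
    path.write_text(f">chr1\n{seq}\n")
    return path, seq


@pytest.fixture
def two_gene_gff(tmp_path):
    """Plus-strand gene with two exons and a minus-strand single-exon gene."""
    text = textwrap.dedent(
        """\
        ##gff-version 3
        chr1\ttest\tgene\t1000\t2000\t.\t+\t.\tID=geneA
        chr1\ttest\tmRNA\t1000\t2000\t.\t+\t.\tID=mrnaA;Parent=geneA
        chr1\ttest\texon\t1000\t1200\t.\t+\t.\tID=exonA1;Parent=mrnaA
        chr1\ttest\texon\t1800\t2000\t.\t+\t.\tID=exonA2;Parent=mrnaA
        chr1\ttest\tgene\t10000\t11000\t.\t-\t.\tID=geneB
        chr1\ttest\tmRNA\t10000\t11000\t.\t-\t.\tID=mrnaB;Parent=geneB
        chr1\ttest\texon\t10000\t11000\t.\t-\t.\tID=exonB1;Parent=mrnaB
        """
    )
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path


def make_matrix(columns, chrom="chr1", positions=None, groups=None, samples=None):
    """Build a GenotypeMatrix from a list of dosage columns."""
    columns = [np.asarray(c, dtype=np.int16) for c in columns]
    n = len(columns[0])
    samples = samples or [f"S{i + 1}" for i in range(n)]
    positions = positions or [100 * (j + 1) for j in range(len(columns))]
    markers = [
        MarkerRecord(id=f"m{j + 1}", chrom=chrom, pos=positions[j], ref="A", alt="G")
        for j in range(len(columns))
    ]
    return GenotypeMatrix(samples, markers, np.column_stack(columns), groups or {})


@pytest.fixture
def two_pool_dataset():
    """Moderately differentiated inbred pools, no injected defects."""
    cfg = sim.SimConfig(
        n_per_group=(25, 25),
        n_markers=200,
        fst=0.15,
        inbreeding=0.95,
        missing_rate=0.02,
        seed=11,
    )
    return sim.simulate_dataset(cfg)
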
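"""Shared fixtures: tiny hand-checkable inputs generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from mosaicscan.popio import AlleleFrequencyTable, GenotypeMatrix, PopulationMap


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t101\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0
chr1\t201\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0|1
chr1\t301\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t./.
chr1\t401\t.\tT\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2
chr1\t501\t.\tA\tG\t.\tPASS\t.\tGT\t1|1\t1/1
"""


@pytest.fixture()
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture()
def toy_genotypes():
    """6-site, 6-sample matrix over three populations with hand-known counts."""
    dosage = np.array(
        [
            # OG   OG   A    A    B    B
            [0,    0,   1,   2,   0,   0],
            [0,    0,   0,   1,   1,   2],
            [2,    2,   1,   0,   2,   1],
            [0,    0,   2,   2,   2,   2],
            [0,    -1,  0,   0,   1,   -1],
            [1,    0,   1,   1,   0,   0],   # polarizing population polymorphic
        ],
        dtype=np.int8,
    )
    geno = GenotypeMatrix(
        chrom=np.array(["chr1"] * 6, dtype=object),
        pos=np.arange(0, 600, 100),
        ref=np.array(list("ACGTAC"), dtype=object),
        alt=np.array(list("TGACGA"), dtype=object),
        dosage=dosage,
        samples=["o1", "o2", "a1", "a2", "b1", "b2"],
    )
    pops = PopulationMap(
        {"o1": "OG", "o2": "OG", "a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    )
    return geno, pops


def freq_table(columns: dict[str, list[float]]) -> AlleleFrequencyTable:
    """Build a frequency table from per-population site lists."""
    pops = list(columns)
    freq = np.column_stack([np.asarray(columns[p], dtype=float) for p in pops])
    n = freq.shape[0]
    return AlleleFrequencyTable(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(n, dtype=np.int64),
        freq=freq,
        populations=pops,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
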
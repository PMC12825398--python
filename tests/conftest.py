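"""Shared fixtures: tiny simulated datasets and hand-written variant files."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

import imprintome as im
from imprintome.cli import SIMULATION_FILTERS, refilter_sites


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene simulated dataset with planted MEGs/PEGs (seed 11)."""
    cfg = im.SimConfig(n_genes=200, rng_seed=11)
    truth, sites, genes, counts, designs = im.simulate_dataset(cfg)
    refilter_sites(sites, SIMULATION_FILTERS)
    return {
        "cfg": cfg,
        "truth": truth,
        "sites": sites,
        "genes": genes,
        "counts": counts,
        "designs": designs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2
    """
)


@pytest.fixture()
def parental_vcf(tmp_path):
    """Hand-written two-sample VCF covering well-formed, multiallelic,
    missing-genotype, low-quality and indel rows."""
    body = textwrap.dedent(
        """\
        chr1\t150\t.\tA\tG\t50\tPASS\tDP=40\tGT\t0/0\t1/1
        chr1\t300\t.\tC\tT\t20\tPASS\tDP=5\tGT\t0/0\t1/1
        chr1\t450\t.\tG\tA\t19\tPASS\tDP=50\tGT\t0/0\t1/1
        chr1\t600\t.\tT\tC,G\t80\tPASS\tDP=60\tGT\t0/1\t0/2
        chr1\t750\t.\tA\tC\t60\tPASS\tDP=30\tGT\t0/0\t./.
        chr1\t900\t.\tG\tT\t70\tPASS\tDP=44\tGT\t0/1\t0/0
        chr1\t1050\t.\tA\tACT\t90\tPASS\tDP=33\tGT\t0/0\t1/1
        chr1\t1200\t.\tC\tG\t55\tPASS\tDP=25\tGT\t0/1\t0/1
        """
    )
    path = tmp_path / "parents.vcf"
    path.write_text(VCF_HEADER + body)
    return path
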
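import textwrap

import numpy as np
import pandas as pd
import pytest

from toxmod.synthetic import SimulationConfig, NetworkConfig


@pytest.fixture
def toy_vcf(tmp_path):
    """3 records, one tri-allelic; mixed GT encodings; DP present."""
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
        ##contig=<ID=1,length=100000>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
        1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:30\t1|1:25\t./.:10
        1\t200\trs2\tC\tT,G\t.\tPASS\t.\tGT:DP\t0/1:30\t0/0:30\t0/2:30
        1\t300\trs3\tG\tA\t.\tq10\t.\tGT:DP\t0/0:30\t0/1:30\t1/1:30
        """
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_network_tsv(tmp_path):
    rows = [
        ("A", "B", 900),
        ("B", "C", 700),
        ("C", "D", 650),
        ("B", "A", 850),  # duplicate reversed, lower score
        ("E", "E", 999),  # self loop
        ("A", "C", 800),
    ]
    path = tmp_path / "net.tsv"
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tcombined_score\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n")
    return path


@pytest.fixture(scope="session")
def small_config():
    """Small-but-realistic config for fast pipeline tests.

    Verified to yield a non-empty toxicity module and a fitted model in both
    pipeline modes at this seed.
    """
    return SimulationConfig(
        n_variants=300,
        rng_seed=3,
        n_causal=8,
        causal_odds_ratio=8.0,
        liability_noise_scale=0.3,
        phenotype_noise_sd=0.5,
        causal_maf_range=(0.4, 0.5),
        fraction_genic=0.7,
        network=NetworkConfig(n_module_genes=25, n_background_genes=150, p_in=0.85, p_out=0.03),
    )


@pytest.fixture
def grade_table():
    """96 samples whose maximal-toxicity classes are 54 high / 8 int / 34 low."""
    grades = [3] * 15 + [4] * 39 + [2] * 8 + [0] * 23 + [1] * 11
    rng = np.random.default_rng(0)
    comp = np.minimum(np.array(grades), rng.integers(0, 5, size=96))
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(96)],
            "grade_neutropenia": np.maximum(comp, 0),
            "grade_leukopenia": comp,
            "grade_thrombocytopenia": comp,
            "grade_maximal": grades,
        }
    )
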
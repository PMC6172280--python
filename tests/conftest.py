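import numpy as np
import pandas as pd
import pytest

from twaskit.synthetic_data import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def geno(cfg):
    """A small reference locus: 300 samples x 12 SNPs with AR(1) LD."""
    return simulate_genotypes(cfg, n=300, p=12, rng=np.random.default_rng(7))


@pytest.fixture()
def sumstats_file(tmp_path):
    """Well-formed 3-row summary-statistic TSV."""
    path = tmp_path / "ss.tsv"
    pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["1", "1", "1"],
            "BP": [100, 200, 300],
            "A1": ["A", "C", "G"],
            "A2": ["G", "T", "A"],
            "Z": [1.5, -0.7, 2.2],
            "MAF": [0.2, 0.3, 0.1],
            "N": [1000, 1000, 1000],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
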
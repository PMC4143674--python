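import numpy as np
import pandas as pd
import pytest

from pedstruct import SimConfig, simulate_study, validate_pedigree
from pedstruct.genotypes import GenotypeMatrix


def trio_records():
    return [
        dict(fid="T", iid="dad", father=None, mother=None, sex=1, genotyped=True),
        dict(fid="T", iid="mom", father=None, mother=None, sex=2, genotyped=True),
        dict(fid="T", iid="child", father="dad", mother="mom", sex=1,
             genotyped=True),
    ]


def three_gen_records():
    # founders A,B; their child C; marry-in D; grandchild E of (C, D)
    return [
        dict(fid="G", iid="A", father=None, mother=None, sex=1, genotyped=True),
        dict(fid="G", iid="B", father=None, mother=None, sex=2, genotyped=True),
        dict(fid="G", iid="C", father="A", mother="B", sex=1, genotyped=True),
        dict(fid="G", iid="D", father=None, mother=None, sex=2, genotyped=True),
        dict(fid="G", iid="E", father="C", mother="D", sex=2, genotyped=True),
    ]


@pytest.fixture
def trio_ped():
    return validate_pedigree(trio_records())


@pytest.fixture
def three_gen_ped():
    return validate_pedigree(three_gen_records())


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared by read-only tests."""
    cfg = SimConfig(n_families=4, family_size_range=(8, 18), n_snps=250,
                    seed=7, missing_rate=0.02)
    return simulate_study(cfg)


def make_matrix(dosages, fids=None):
    """GenotypeMatrix from a raw array, one synthetic SNP record per column."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    fids = fids or ["F1"] * n
    samples = [(fids[i], f"s{i + 1}") for i in range(n)]
    snps = pd.DataFrame(dict(
        snp_id=[f"rs{j + 1}" for j in range(m)], chrom="1",
        pos=[1000 * (j + 1) for j in range(m)], ref="A", alt="G"))
    return GenotypeMatrix(d, samples, snps)
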
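import numpy as np
import pytest

from momics_smr import simulate as sim
from momics_smr.sumstats_io import AssocDataset, VariantStat


def make_stat(snp="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
              beta=0.1, se=0.02, p=None, n=10_000.0):
    from scipy import stats as st

    if p is None:
        p = float(2 * st.norm.sf(abs(beta / se)))
        p = min(max(p, 1e-300), 1.0)
    return VariantStat(snp, chrom, pos, ea, oa, eaf, beta, se, p, n)


@pytest.fixture
def std_region():
    """AR(1) rho=0.8 region of 41 SNPs, fixed seed, shared across tests."""
    return sim.simulate_region(sim.RegionSpec(m_snps=41, rho=0.8, seed=0))


@pytest.fixture
def small_dataset():
    recs = [
        make_stat("rs1", pos=1000, ea="A", oa="G", eaf=0.3, beta=0.10, se=0.02),
        make_stat("rs2", pos=2000, ea="C", oa="T", eaf=0.4, beta=-0.05, se=0.02),
        make_stat("rs3", pos=3000, ea="G", oa="A", eaf=0.2, beta=0.01, se=0.02),
    ]
    return AssocDataset("trait", "quantitative", recs)


def dataset_to_tsv(dataset, path):
    from momics_smr.sumstats_io import write_sumstats

    write_sumstats(dataset, str(path))
    return str(path)
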
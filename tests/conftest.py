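import numpy as np
import pytest

from methvc import kinship
from methvc import simulate as sim


@pytest.fixture(scope="session")
def desk_cohort():
    """One desk-scale twin cohort (200 MZ + 200 DZ pairs, 500 SNPs) shared
    across tests that only need structure, not fresh randomness."""
    cfg = sim.desk_config(n_sites=1, seed=42)
    ped = sim.simulate_pedigree(cfg)
    geno, snp_info = sim.simulate_genotypes(ped, cfg)
    cov = sim.simulate_covariates(ped, cfg)
    return {"config": cfg, "ped": ped, "geno": geno, "snps": snp_info, "cov": cov}


@pytest.fixture(scope="session")
def desk_grms(desk_cohort):
    g_ibs = kinship.compute_grm(desk_cohort["geno"])
    g_ibd = kinship.threshold_grm(g_ibs)
    g_ped = kinship.pedigree_kinship(desk_cohort["ped"])
    return {"ibs": g_ibs, "ibd": g_ibd, "ped": g_ped}


@pytest.fixture(scope="session")
def family_labels(desk_cohort):
    return desk_cohort["ped"]["family_id"].to_numpy()
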
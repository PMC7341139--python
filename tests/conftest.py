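import numpy as np
import pandas as pd
import pytest

import gremlite as gl
from gremlite.greml import MixedModelData, make_design
from gremlite.io_formats import GenotypeData


def make_genotypes(dosages, iids=None) -> GenotypeData:
    """GenotypeData from a raw dosage matrix with autogenerated metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    iids = iids if iids is not None else [f"I{i:04d}" for i in range(n)]
    sample = pd.DataFrame({"fid": iids, "iid": iids, "sex": 1})
    snps = pd.DataFrame({
        "chrom": 1, "snp": [f"s{j:05d}" for j in range(m)],
        "pos": np.arange(1, m + 1), "a1": "A", "a2": "G",
    })
    return GenotypeData(d, snps, sample)


def simulate_mixed_data(seed, n, m, h2, n_causal=None, covars=False):
    """Simulated cohort wired into a MixedModelData plus simulation truth."""
    rng = np.random.default_rng(seed)
    geno, gt = gl.simulate_genotypes(gl.GenoSimSpec(n=n, m=m, seed=seed), rng)
    spec = gl.PhenoSimSpec(traits=["t"], h2=[h2],
                           n_causal=n_causal or min(m, max(m // 2, 1)),
                           seed=seed)
    pheno, pt = gl.simulate_phenotypes(geno, spec, rng)
    z = gl.adjust_and_zscore(pheno, "t").sort_values("iid")
    grm = gl.compute_grm(geno)
    if covars:
        meta = geno.sample_meta.set_index("iid").loc[z["iid"]]
        X = make_design(meta[["prefecture", "platform"]].reset_index(drop=True))
    else:
        X = make_design(n=n)
    data = MixedModelData(y=z["z"].to_numpy(), X=X, G=grm.values,
                          ids=z["iid"].to_numpy())
    return data, pt


@pytest.fixture(scope="session")
def small_cohort():
    """60 x 300 cohort with missingness, shared across read-only tests."""
    geno, truth = gl.simulate_genotypes(
        gl.GenoSimSpec(n=60, m=300, maf_range=(0.1, 0.5),
                       missing_rate=0.03, seed=11))
    return geno, truth


@pytest.fixture(scope="session")
def reference_matrices():
    return gl.load_reference_correlations()
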
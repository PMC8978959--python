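import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import HarmonizedSet
from mrmediate.mvmr import MVHarmonizedSet


def make_harmonized(gamma, se_gamma, Gamma, se_Gamma, ids=None) -> HarmonizedSet:
    gamma = np.asarray(gamma, float)
    n = gamma.size
    ids = ids or [f"rs{i + 1}" for i in range(n)]
    table = pd.DataFrame({
        "snp_id": ids,
        "gamma": gamma,
        "se_gamma": np.asarray(se_gamma, float),
        "Gamma": np.asarray(Gamma, float),
        "se_Gamma": np.asarray(se_Gamma, float),
        "allele_flipped": False, "proxy_substituted": False,
        "palindromic_inferred": False, "proxy_id": "",
    })
    return HarmonizedSet(table=table, exposure_trait="x", outcome_trait="y")


def make_mv(G, SE_G, Gamma, se_Gamma, labels=("x1", "x2")) -> MVHarmonizedSet:
    G = np.atleast_2d(np.asarray(G, float))
    SE_G = np.atleast_2d(np.asarray(SE_G, float))
    n = G.shape[0]
    data = {"snp_id": [f"rs{i + 1}" for i in range(n)]}
    for k, lbl in enumerate(labels):
        data[f"gamma_{lbl}"] = G[:, k]
        data[f"se_gamma_{lbl}"] = SE_G[:, k]
    data["Gamma"] = np.asarray(Gamma, float)
    data["se_Gamma"] = np.asarray(se_Gamma, float)
    return MVHarmonizedSet(table=pd.DataFrame(data), exposures=list(labels))


@pytest.fixture
def three_snp_set() -> HarmonizedSet:
    """Small fixed set with mild heterogeneity, used across estimator tests."""
    return make_harmonized(
        gamma=[0.10, 0.20, 0.15],
        se_gamma=[0.01, 0.01, 0.02],
        Gamma=[0.05, 0.09, 0.08],
        se_Gamma=[0.02, 0.03, 0.025],
    )
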
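import numpy as np
import pandas as pd
import pytest

from runjkit.genemodel import GeneModel
from runjkit.signatures import SBS96_CONTEXTS, Exposures, SignatureCatalog
from runjkit.synthetic import toy_gene_model


@pytest.fixture(scope="session")
def gm_plus() -> GeneModel:
    return toy_gene_model(strand="+")


@pytest.fixture(scope="session")
def gm_minus() -> GeneModel:
    return toy_gene_model(strand="-")


@pytest.fixture(scope="session")
def catalog_pair() -> SignatureCatalog:
    """Two well-separated synthetic signatures: one on C:G pairs, one on T:A.

    Disjoint context support makes per-mutation attribution unambiguous, so
    mixture-recovery tests reduce to binomial sampling noise.
    """
    probs = pd.DataFrame(0.0, index=list(SBS96_CONTEXTS), columns=["SIG_C", "SIG_T"])
    c_ctx = [c for c in SBS96_CONTEXTS if c[2] == "C"]
    t_ctx = [c for c in SBS96_CONTEXTS if c[2] == "T"]
    probs.loc[c_ctx, "SIG_C"] = 1.0 / len(c_ctx)
    probs.loc[t_ctx, "SIG_T"] = 1.0 / len(t_ctx)
    return SignatureCatalog(probs)


@pytest.fixture(scope="session")
def exposures_even(catalog_pair) -> Exposures:
    w = pd.DataFrame(
        {"SIG_C": [0.5], "SIG_T": [0.5]}, index=pd.Index(["sim"], name="sample")
    )
    return Exposures(w)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
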
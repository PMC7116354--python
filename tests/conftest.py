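import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

import gwasprio as gp
from gwasprio.mapping import EquivalenceClasses

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy():
    """Small synthetic GWAS with pathway-enriched signal."""
    stats, coords, genesets, delta = gp.toy_dataset(seed=1)
    return {"stats": stats, "coords": coords, "genesets": genesets, "delta": delta}


@pytest.fixture(scope="session")
def toy_reweight(toy):
    """Full pipeline run (both schemes, CV-selected penalty) on the toy data."""
    return gp.reweight(toy["stats"], toy["coords"], toy["genesets"],
                       scheme="both", lam="cv", n_lambda=30, seed=3)


def make_eqclasses(V, psibar, sizes, names=None):
    """Build an EquivalenceClasses object directly from class-level arrays."""
    V = sp.csr_matrix(np.asarray(V, dtype=np.int8))
    sizes = np.asarray(sizes, dtype=np.int64)
    class_of_snp = np.repeat(np.arange(len(sizes)), sizes)
    names = names or [f"A{k}" for k in range(V.shape[1])]
    eq = EquivalenceClasses(class_of_snp, V, sizes, names)
    if psibar is not None:
        eq = eq.with_psibar(np.asarray(psibar, dtype=float))
    return eq


@pytest.fixture(scope="session")
def two_class_eq():
    """Two classes, one annotated: closed-form logistic solution exists."""
    return make_eqclasses([[1], [0]], [0.7, 0.2], [1, 1])
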
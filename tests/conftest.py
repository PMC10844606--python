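import numpy as np
import pandas as pd
import pytest

import opbreed as ob


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small mixed-sibship OP dataset shared by read-only tests."""
    cfg = ob.SimConfig(
        n_families=6,
        offspring_per_family_per_site=5,
        n_sites=2,
        n_snps=300,
        n_qtl_per_trait=30,
        seed=11,
    )
    return ob.simulate_dataset(cfg)


@pytest.fixture()
def single_snp_genotypes():
    """The worked single-SNP example: codes 0/1/2, p = 0.5."""
    return ob.GenotypeMatrix(["a", "b", "c"], ["snp1"], np.array([[0.0], [1.0], [2.0]]))


def make_bvs(ids, bv, trait="HT", site="S1", label="X"):
    from opbreed.mixed_models import BreedingValueSet

    return BreedingValueSet(
        pd.DataFrame(
            {"id": ids, "trait": trait, "site": site, "bv": bv, "pev": 0.0}
        ),
        label,
    )
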
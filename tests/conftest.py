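from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import neuroqsp as nq
from neuroqsp.genotypes import enumerate_genotypes
from neuroqsp.signals import PathologyParams, reference_signals

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def drug_profiles():
    return nq.load_drug_profiles()


@pytest.fixture(scope="session")
def pathology():
    return PathologyParams()


@pytest.fixture(scope="session")
def reference_loop_signals(pathology):
    """Signals of the untreated reference heterozygote as the loops consume them."""
    cortical = reference_signals(pathology, "cortical")
    return {
        **reference_signals(pathology, "striatal"),
        "5HT2A": cortical["5HT2A"],
        "5HT1A": cortical["5HT1A"],
        "D1_cortical": cortical["D1"],
    }


@pytest.fixture(scope="session")
def table4_totals():
    """The published 27-genotype x 7-drug total-rank matrix (regression fixture)."""
    from neuroqsp.study import read_rank_totals

    return read_rank_totals(DATA / "table4_ranks.csv")


@pytest.fixture()
def synthetic_outcomes():
    """Deterministic synthetic standard-dose outcome table over all 27 genotypes."""
    rng = np.random.default_rng(7)
    drugs = list(nq.DRUG_ORDER)
    rows = []
    for endpoint in ("panss", "eps", "cognition"):
        for g in enumerate_genotypes():
            for d in drugs:
                rows.append(
                    {
                        "drug": d,
                        "dose_fraction": 1.0,
                        "dose_mg": 1.0,
                        "genotype": str(g),
                        "endpoint": endpoint,
                        "seed": 0,
                        "raw": 0.0,
                        "value": float(rng.normal()),
                    }
                )
    return pd.DataFrame(rows)
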
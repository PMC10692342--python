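import numpy as np
import pandas as pd
import pytest

from heatnorm import simulate as sim
from heatnorm import editing


TINY = dict(
    n_herds=4, n_stations=3, n_years=5, n_dams=120, n_sires=16,
    n_genotyped_sires=12, n_snps=150,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete synthetic dataset shared across test modules."""
    cfg = sim.reference_regime_config(**TINY)
    return sim.simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_edited(tiny_dataset):
    edited, _ = editing.edit_phenotypes(tiny_dataset.calves)
    edited = editing.assign_classes(edited)
    return edited.merge(tiny_dataset.covariates, on="calf_id")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pedigree(rng, n_founders=4, n_total=12):
    """Random acyclic pedigree: animal i's parents drawn from earlier animals."""
    ids = [f"A{i}" for i in range(n_total)]
    rows = []
    for i, a in enumerate(ids):
        if i < n_founders:
            rows.append((a, 0, 0))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            rows.append((a, ids[s], ids[d]))
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])
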
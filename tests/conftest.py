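import numpy as np
import pandas as pd
import pytest

from kinliab import GeneratingModel, simulate_univariate_pairs


@pytest.fixture(scope="session")
def sibling_cohort_small():
    """Moderate sibling cohort under known truth (a2=0.5, c2=0.2, K=0.2)."""
    model = GeneratingModel.univariate(0.5, 0.2, 0.2)
    return simulate_univariate_pairs(
        model, n_by_pair_type={"FS": 50000, "MHS": 25000, "PHS": 25000},
        seed=11)


@pytest.fixture()
def toy_pairs():
    """Hand-built 10-pair table with both traits, enumerable by eye."""
    rows = []
    layout = [
        # (pair_type, t1_m1, t1_m2, t2_m1, t2_m2)
        ("FS", 1, 0, 1, 1),
        ("FS", 0, 0, 0, 0),
        ("FS", 0, 0, 1, 0),
        ("FS", 1, 1, 1, 1),
        ("FS", 0, 0, 0, 0),
        ("FS", 0, 1, 0, 1),
        ("MHS", 0, 0, 0, 0),
        ("MHS", 1, 0, 0, 0),
        ("MHS", 0, 0, 0, 1),
        ("MHS", 0, 0, 1, 1),
    ]
    for i, (pt, a, b, c, d) in enumerate(layout):
        rows.append({"pair_id": i, "pair_type": pt,
                     "trait1_m1": a, "trait1_m2": b,
                     "trait2_m1": c, "trait2_m2": d,
                     "sex_m1": 1, "sex_m2": 2,
                     "birthyear_m1": 1960, "birthyear_m2": 1962})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160503)
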
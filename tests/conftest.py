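import numpy as np
import pytest
from hypothesis import settings

from polyblup import Pedigree

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def trio_pedigree():
    """Two founders and their daughter."""
    return Pedigree([("F1", None, None, "F"), ("M1", None, None, "M"),
                     ("P1", "F1", "M1", "F")])


@pytest.fixture
def fullsib_pedigree():
    """Founders, two full sibs, and the full-sib-mating offspring."""
    return Pedigree([
        ("F1", None, None, "F"), ("M1", None, None, "M"),
        ("S1", "F1", "M1", "F"), ("S2", "F1", "M1", "M"),
        ("K", "S1", "S2", "F"),
    ])


def random_pedigree(rng, n_founders=4, n_generations=3, per_gen=4,
                    p_missing=0.15):
    """Random pedigree of depth <= n_generations + 1 for oracle checks."""
    recs = [(f"G0_{i}", None, None, "U") for i in range(n_founders)]
    pool = [r[0] for r in recs]
    for g in range(1, n_generations + 1):
        new = []
        for i in range(per_gen):
            s = None if rng.random() < p_missing else pool[rng.integers(len(pool))]
            d = None if rng.random() < p_missing else pool[rng.integers(len(pool))]
            iid = f"G{g}_{i}"
            recs.append((iid, s, d, "U"))
            new.append(iid)
        pool = pool + new
    return Pedigree(recs)
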
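import numpy as np
import pandas as pd
import pytest

from mstnassoc.pedigree import Pedigree


@pytest.fixture
def textbook_pedigree() -> Pedigree:
    """Two founders, two full sibs, one inbred full-sib offspring."""
    return Pedigree.from_frame(pd.DataFrame({
        "animal": ["s", "d", "a", "b", "x"],
        "sire": [None, None, "s", "s", "a"],
        "dam": [None, None, "d", "d", "b"],
    }))


def random_pedigree(n_founders=20, n_per_gen=60, n_gen=3, seed=0) -> Pedigree:
    rng = np.random.default_rng(seed)
    rows = [{"animal": f"f{i}", "sire": None, "dam": None} for i in range(n_founders)]
    males = [f"f{i}" for i in range(0, n_founders, 2)]
    females = [f"f{i}" for i in range(1, n_founders, 2)]
    for g in range(n_gen):
        newm, newf = [], []
        for k in range(n_per_gen):
            a = f"g{g}_{k}"
            rows.append({"animal": a,
                         "sire": males[int(rng.integers(len(males)))],
                         "dam": females[int(rng.integers(len(females)))]})
            (newm if rng.random() < 0.5 else newf).append(a)
        males += newm
        females += newf
    return Pedigree.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def medium_pedigree() -> Pedigree:
    return random_pedigree(n_founders=20, n_per_gen=60, n_gen=3, seed=1)
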
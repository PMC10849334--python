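import numpy as np
import pandas as pd
import pytest

from abweight.data import Dataset, MarkerMatrix, PhenotypeTable


@pytest.fixture
def tiny_dataset() -> Dataset:
    """3 lines x 2 polymorphic markers, 1 environment, 1 trait."""
    markers = MarkerMatrix.from_dosage(
        np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
        ["L1", "L2", "L3"],
        ["mA", "mB"],
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "line": ["L1", "L2", "L3"],
                "family": ["FamA", "FamA", "FamB"],
                "env": "E1",
                "trait": "yield",
                "value": [1.0, 2.0, 3.0],
            }
        )
    )
    return Dataset(markers, pheno)


def make_family_dataset(
    seed: int = 0,
    n_families: int = 3,
    lines_per_family: int = 8,
    p: int = 40,
    h2: float = 0.5,
) -> Dataset:
    """Small multi-family dataset with Hardy-Weinberg genotypes."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.2, 0.8, size=p)
    X, lines, fams = [], [], []
    for f in range(n_families):
        X.append(rng.binomial(2, freq, size=(lines_per_family, p)).astype(float))
        lines += [f"F{f}_L{j}" for j in range(lines_per_family)]
        fams += [f"F{f}"] * lines_per_family
    X = np.vstack(X)
    markers = MarkerMatrix.from_dosage(X, lines, [f"m{k}" for k in range(p)])
    beta = rng.standard_normal(markers.p)
    g = markers.M @ beta
    g *= np.sqrt(h2) / g.std()
    y = 10.0 + g + rng.standard_normal(len(lines)) * np.sqrt(1 - h2)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"line": lines, "family": fams, "env": "E1", "trait": "t1", "value": y}
        )
    )
    return Dataset(markers, pheno)


@pytest.fixture
def family_dataset() -> Dataset:
    return make_family_dataset()
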
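import numpy as np
import pandas as pd
import pytest

from trialqg import PhenotypeTable, TrialDesign


def long_frame(values, years=("Y1",), regimes=("R1",)):
    """Build a tidy frame from {trait: genotype x block array} per (year, regime).

    ``values`` maps (year, regime, trait) -> 2-D array (genotypes x blocks),
    or trait -> array when there is a single year and regime.
    """
    rows = []
    if all(isinstance(k, str) for k in values):
        values = {(years[0], regimes[0], t): v for t, v in values.items()}
    for (year, regime, trait), arr in values.items():
        arr = np.asarray(arr, float)
        g, r = arr.shape
        for i in range(g):
            for j in range(r):
                rows.append(
                    dict(
                        genotype=f"G{i + 1}", year=year, regime=regime,
                        block=f"B{j + 1}", trait=trait, value=arr[i, j],
                    )
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_table():
    """3 genotypes x 2 blocks, one trait, hand-set values."""
    arr = [[10.0, 12.0], [14.0, 13.0], [20.0, 23.0]]
    return PhenotypeTable(long_frame({"T": arr}))


@pytest.fixture
def toy_bivariate():
    """3 genotypes x 2 blocks, two traits on the same units."""
    x = [[10.0, 12.0], [14.0, 13.0], [20.0, 23.0]]
    y = [[1.0, 2.0], [3.0, 2.5], [5.0, 6.0]]
    return PhenotypeTable(long_frame({"X": x, "Y": y}))


@pytest.fixture
def small_design():
    return TrialDesign(
        n_genotypes=2, n_blocks=2, years=("Y1",), regimes=("R1",), traits=("T",)
    )


def random_balanced_table(rng, g=4, r=3, traits=("X", "Y"), years=("Y1",), regimes=("R1",)):
    vals = {
        (yr, reg, t): rng.normal(50, 10, size=(g, r))
        for t in traits
        for yr in years
        for reg in regimes
    }
    return PhenotypeTable(long_frame(vals, years=years, regimes=regimes))
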
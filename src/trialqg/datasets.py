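"""Bundled reference data.

``load_trial_summary`` returns the per-trait genetic summary published
for a two-year (2018–2019) deficit-irrigation field evaluation of 100
Kentucky bluegrass (*Poa pratensis*) ecotypes: trait means ± SE under a
well-watered control and a 50%-deficit drought regime, with the
genotypic and phenotypic coefficients of variation, broad-sense
heritability, genetic advance and GAM for each trait × year × regime.

These printed statistics serve two purposes: worked examples on real
numbers, and consistency checks of the estimator identities
(h² = 100·(GCV/PCV)², GAM = 100·GA/μ, GA = k·σp·h²/100) that hold by
construction for any summary produced by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TRAITS = ("FY", "DY", "A", "gs", "Tr", "Chl", "FvFm")
YIELD_TRAITS = ("FY", "DY")
PHOTOSYNTHETIC_TRAITS = ("A", "gs", "Tr", "Chl", "FvFm")


def load_trial_summary() -> pd.DataFrame:
    """Published bluegrass trial summary, one row per trait × year × regime.

    Columns: trait, year, regime, mean, se, gcv, pcv, h2, ga, gam.
    ``FY``/``DY`` are fresh/dry forage yield (g/plot); ``A``, ``gs``,
    ``Tr`` leaf gas exchange; ``Chl`` chlorophyll content; ``FvFm`` PSII
    photochemical efficiency.
    """
    ref = resources.files("trialqg").joinpath("data/bluegrass_trial_summary.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"year": str})
    return df


def summary_row(df: pd.DataFrame, trait: str, year, regime: str) -> pd.Series:
    """Pick one trait × year × regime row of the summary."""
    m = (df["trait"] == trait) & (df["year"] == str(year)) & (df["regime"] == regime)
    sub = df[m]
    if len(sub) != 1:
        raise KeyError(f"no unique row for {trait}/{year}/{regime}")
    return sub.iloc[0]
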
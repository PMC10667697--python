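"""Balanced ANOVA for RCBD trials and the combined multi-environment table.

Per environment-year the model is the classical randomized complete
block decomposition  y_ij = μ + g_i + b_j + e_ij  with expected mean
squares E[MS_genotype] = σe² + r σg² and E[MS_error] = σe², which is
what the downstream variance-component estimators invert.

The combined analysis treats the two-year × two-regime layout as a
split-plot-in-time factorial with blocks nested in regime:

    Ir                tested against Error I  = R(M)
    G, Ir×G           tested against Error II = R×G(M)
    Y, Y×Ir, Y×G, Y×G×Ir  tested against the pooled Residual

All sums of squares come from marginal means of the balanced layout,
so they are exact (no iterative fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .trial import PhenotypeTable

COMBINED_SOURCES = [
    "Ir", "Error I", "G", "Ir x G", "Error II",
    "Y", "Y x Ir", "Y x G", "Y x G x Ir", "Residual",
]

# F-test denominator for each testable source (split-plot-in-time convention)
_F_DENOM = {
    "Ir": "Error I",
    "G": "Error II",
    "Ir x G": "Error II",
    "Y": "Residual",
    "Y x Ir": "Residual",
    "Y x G": "Residual",
    "Y x G x Ir": "Residual",
}


@dataclass
class AnovaTable:
    """RCBD ANOVA for one trait in one environment-year.

    ``table`` has one row per source (block, genotype, error) with df,
    SS, MS, F and p; ``ms_genotype``/``ms_error`` and the design sizes
    feed the expected-mean-squares variance-component estimators.
    """

    trait: str
    year: str
    regime: str
    table: pd.DataFrame
    n_genotypes: int
    n_blocks: int
    grand_mean: float
    effects_metadata: dict = field(
        default_factory=lambda: {"genotype": "fixed", "block": "random"}
    )

    @property
    def ms_genotype(self) -> float:
        return float(self.table.loc["genotype", "MS"])

    @property
    def ms_error(self) -> float:
        return float(self.table.loc["error", "MS"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "source", out.index)
        return out.reset_index(drop=True)


@dataclass
class CombinedAnovaTable:
    """Combined factorial ANOVA across years and regimes for one trait."""

    trait: str
    table: pd.DataFrame  # indexed by COMBINED_SOURCES

    @property
    def df_vector(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.table["df"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "source", out.index)
        return out.reset_index(drop=True)


def _balanced_matrix(
    table: PhenotypeTable, trait: str, year, regime
) -> pd.DataFrame:
    sub = table.subset(trait=trait, year=year, regime=regime)
    if sub.empty:
        raise DesignError(
            f"no data for trait={trait!r}, year={year!r}, regime={regime!r}"
        )
    mat = sub.pivot(index="genotype", columns="block", values="value")
    if mat.isna().any().any():
        raise DesignError(
            f"unbalanced subset for trait={trait!r}, year={year!r}, "
            f"regime={regime!r}: missing genotype x block cells"
        )
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise DesignError(
            f"RCBD ANOVA needs >=2 genotypes and >=2 blocks, got {mat.shape}"
        )
    return mat


def rcbd_anova(table: PhenotypeTable, trait: str, year, regime) -> AnovaTable:
    """Two-way (genotype + block) decomposition of one balanced subset.

    Sums of squares from marginal means:
      SS_genotype = r Σ_i (ȳ_i. − ȳ)²,  SS_block = g Σ_j (ȳ_.j − ȳ)²,
      SS_error by subtraction from SS_total (equals the interaction SS,
      which is the RCBD residual).
    """
    mat = _balanced_matrix(table, trait, year, regime)
    y = mat.to_numpy(float)
    g, r = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_geno = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_block = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_geno - ss_block, 0.0)

    df_geno, df_block = g - 1, r - 1
    df_error = (g - 1) * (r - 1)
    rows = {
        "block": (df_block, ss_block),
        "genotype": (df_geno, ss_geno),
        "error": (df_error, ss_error),
    }
    tab = pd.DataFrame(
        {
            "df": {k: v[0] for k, v in rows.items()},
            "SS": {k: v[1] for k, v in rows.items()},
        }
    )
    tab["MS"] = tab["SS"] / tab["df"]
    ms_e = tab.loc["error", "MS"]
    tab["F"] = np.nan
    tab["p"] = np.nan
    if ms_e > 0:
        for src in ("block", "genotype"):
            f = tab.loc[src, "MS"] / ms_e
            tab.loc[src, "F"] = f
            tab.loc[src, "p"] = stats.f.sf(f, tab.loc[src, "df"], df_error)
    return AnovaTable(
        trait=trait,
        year=str(year),
        regime=regime,
        table=tab,
        n_genotypes=g,
        n_blocks=r,
        grand_mean=float(grand),
    )


def combined_anova(table: PhenotypeTable, trait: str) -> CombinedAnovaTable:
    """Combined ANOVA over years × regimes with blocks nested in regime.

    Requires a balanced layout with at least 2 years and 2 regimes.  For
    a g = 100, r = 2, 2-year, 2-regime trial the df column is
    (1, 2, 99, 99, 198, 1, 1, 99, 99, 200), summing to 2·2·2·100 − 1.
    """
    sub = table.subset(trait=trait)
    if sub.empty:
        raise DesignError(f"no data for trait {trait!r}")
    years = sorted(sub["year"].unique())
    regimes = sorted(sub["regime"].unique())
    if len(years) < 2 or len(regimes) < 2:
        raise DesignError("combined ANOVA needs >=2 years and >=2 regimes")

    cube = sub.set_index(["year", "regime", "genotype", "block"])["value"]
    try:
        arr = cube.unstack(["year", "regime", "block"])  # genotypes x (y,i,b)
    except ValueError as exc:  # duplicate labels
        raise DesignError(str(exc)) from exc
    full = arr.to_numpy(float)
    if np.isnan(full).any():
        raise DesignError(f"unbalanced layout for trait {trait!r}")

    # reshape to y[year, regime, genotype, block]
    genos = list(arr.index)
    blocks = sorted(sub["block"].unique())
    ny, ni, ng, nr = len(years), len(regimes), len(genos), len(blocks)
    y = np.empty((ny, ni, ng, nr))
    for a, yr in enumerate(years):
        for b, reg in enumerate(regimes):
            for c, blk in enumerate(blocks):
                y[a, b, :, c] = arr[(yr, reg, blk)].to_numpy(float)

    grand = y.mean()
    n_total = y.size

    def dev(axis_keep):
        """Marginal mean over all axes except axis_keep, minus grand mean."""
        axes = tuple(a for a in range(4) if a not in axis_keep)
        return y.mean(axis=axes) - grand

    # Main-effect deviations
    d_y = dev((0,))          # year
    d_i = dev((1,))          # regime
    d_g = dev((2,))          # genotype
    m_yi = dev((0, 1))       # year x regime margin (deviation from grand)
    m_yg = dev((0, 2))
    m_ig = dev((1, 2))
    m_ib = dev((1, 3))       # regime x block margin
    m_yig = dev((0, 1, 2))

    ss = {}
    ss["Ir"] = float(ny * ng * nr * (d_i ** 2).sum())
    # blocks within regime, averaged over years and genotypes
    ss["Error I"] = float(
        ny * ng * ((m_ib - d_i[:, None]) ** 2).sum()
    )
    ss["G"] = float(ny * ni * nr * (d_g ** 2).sum())
    ss["Ir x G"] = float(
        ny * nr * ((m_ig - d_i[:, None] - d_g[None, :]) ** 2).sum()
    )
    # replicate x genotype within regime, averaged over years
    m_igb = y.mean(axis=0) - grand  # regime x genotype x block
    ss["Error II"] = float(
        ny
        * (
            (m_igb - m_ig[:, :, None] - m_ib[:, None, :] + d_i[:, None, None]) ** 2
        ).sum()
    )
    ss["Y"] = float(ni * ng * nr * (d_y ** 2).sum())
    ss["Y x Ir"] = float(
        ng * nr * ((m_yi - d_y[:, None] - d_i[None, :]) ** 2).sum()
    )
    ss["Y x G"] = float(
        ni * nr * ((m_yg - d_y[:, None] - d_g[None, :]) ** 2).sum()
    )
    ss["Y x G x Ir"] = float(
        nr
        * (
            (
                m_yig
                - m_yi[:, :, None]
                - m_yg[:, None, :]
                - m_ig[None, :, :]
                + d_y[:, None, None]
                + d_i[None, :, None]
                + d_g[None, None, :]
            )
            ** 2
        ).sum()
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss["Residual"] = max(ss_total - sum(ss.values()), 0.0)

    df = {
        "Ir": ni - 1,
        "Error I": ni * (nr - 1),
        "G": ng - 1,
        "Ir x G": (ni - 1) * (ng - 1),
        "Error II": ni * (nr - 1) * (ng - 1),
        "Y": ny - 1,
        "Y x Ir": (ny - 1) * (ni - 1),
        "Y x G": (ny - 1) * (ng - 1),
        "Y x G x Ir": (ny - 1) * (ni - 1) * (ng - 1),
        "Residual": (ny - 1) * ni * (nr - 1) * ng,
    }
    assert sum(df.values()) == n_total - 1

    tab = pd.DataFrame(
        {
            "df": pd.Series(df),
            "SS": pd.Series(ss),
        }
    ).loc[COMBINED_SOURCES]
    tab["MS"] = tab["SS"] / tab["df"]
    tab["F"] = np.nan
    tab["p"] = np.nan
    for src, denom in _F_DENOM.items():
        ms_d = tab.loc[denom, "MS"]
        if ms_d > 0:
            f = tab.loc[src, "MS"] / ms_d
            tab.loc[src, "F"] = f
            tab.loc[src, "p"] = stats.f.sf(f, tab.loc[src, "df"], tab.loc[denom, "df"])
    return CombinedAnovaTable(trait=trait, table=tab)


def combined_df_vector(
    n_genotypes: int, n_blocks: int, n_years: int = 2, n_regimes: int = 2
) -> tuple[int, ...]:
    """Degrees of freedom for each combined-ANOVA source, by bookkeeping alone."""
    g, r, ny, ni = n_genotypes, n_blocks, n_years, n_regimes
    return (
        ni - 1,
        ni * (r - 1),
        g - 1,
        (ni - 1) * (g - 1),
        ni * (r - 1) * (g - 1),
        ny - 1,
        (ny - 1) * (ni - 1),
        (ny - 1) * (g - 1),
        (ny - 1) * (ni - 1) * (g - 1),
        (ny - 1) * ni * (r - 1) * g,
    )
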
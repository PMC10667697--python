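"""Phenotypic and genotypic correlations via mean cross-products.

The bivariate analogue of the RCBD expected-mean-squares analysis: for
each trait pair the genotype and error *mean cross-products* (MCP) are
computed from the same balanced layout, and covariance components follow
the univariate pattern

    Cov_g(X, Y) = (MCP_g − MCP_e) / r,   Cov_e = MCP_e,
    Cov_p = Cov_g + Cov_e.

Correlations are the covariances scaled by the matching standard
deviations:  r_p = Cov_p / (σp(X) σp(Y)),  r_g analogous with genotypic
terms.  Because the genotypic components are method-of-moments
estimates, |r_g| can exceed 1; such entries are reported with a flag and
clamped only for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .trial import PhenotypeTable


@dataclass
class CrossProductComponents:
    """Genotype/error MCP matrices and derived covariance components.

    All matrices are trait × trait DataFrames; the diagonals of
    ``cov_g``/``cov_p`` are the univariate σg²/σp² of each trait.
    """

    traits: list[str]
    mcp_g: pd.DataFrame
    mcp_e: pd.DataFrame
    cov_g: pd.DataFrame
    cov_e: pd.DataFrame
    cov_p: pd.DataFrame
    n_genotypes: int
    n_blocks: int


@dataclass
class CorrelationMatrices:
    """Paired phenotypic and genotypic correlation matrices."""

    r_p: pd.DataFrame
    r_g: pd.DataFrame
    out_of_range_g: pd.DataFrame  # boolean mask where |r_g| > 1

    def clamped_r_g(self) -> pd.DataFrame:
        """r_g clipped to [−1, 1] (for plotting only)."""
        return self.r_g.clip(-1.0, 1.0)

    def paired_triangle(self) -> pd.DataFrame:
        """Single matrix with r_p below and r_g above the unit diagonal."""
        rp, rg = self.r_p.to_numpy(), self.r_g.to_numpy()
        out = np.tril(rp, k=-1) + np.triu(rg, k=1) + np.eye(len(rp))
        return pd.DataFrame(out, index=self.r_p.index, columns=self.r_p.columns)


def _unit_matrix(table: PhenotypeTable, traits, year, regime) -> np.ndarray:
    """(g·r) × traits value matrix with aligned experimental units.

    ``year=None`` pools years by averaging each (genotype, block) cell
    over years before the cross-product analysis.
    """
    sub = table.subset(regime=regime)
    if year is not None:
        sub = sub[sub["year"] == str(year)]
    sub = sub[sub["trait"].isin(traits)]
    if sub.empty:
        raise DesignError("no observations for the requested slice")
    wide = sub.pivot_table(
        index=["genotype", "block"], columns="trait", values="value", aggfunc="mean"
    ).reindex(columns=list(traits))
    if wide.isna().any().any():
        raise DesignError("traits are not observed on identical experimental units")
    return wide


def cross_product_components(
    table: PhenotypeTable,
    traits=None,
    year=None,
    regime=None,
) -> CrossProductComponents:
    """MANOVA mean cross-products for the RCBD layout, one regime slice.

    With ``year=None`` the two (or more) years are pooled by averaging
    genotype × block means, matching a per-regime correlation figure.
    """
    traits = list(traits) if traits is not None else table.traits
    wide = _unit_matrix(table, traits, year, regime)
    genos = wide.index.get_level_values("genotype")
    blocks = wide.index.get_level_values("block")
    g = genos.nunique()
    r = blocks.nunique()
    if g < 2 or r < 2:
        raise DesignError("cross products need >=2 genotypes and >=2 blocks")
    if len(wide) != g * r:
        raise DesignError("unbalanced genotype x block layout")

    X = wide.to_numpy(float)  # (g*r) x t
    grand = X.mean(axis=0)
    gm = wide.groupby(level="genotype").mean().to_numpy(float)  # g x t
    bm = wide.groupby(level="block").mean().to_numpy(float)     # r x t

    dg = gm - grand
    scp_g = r * dg.T @ dg  # genotype sums of cross-products
    # residual after removing genotype and block effects
    geno_codes = pd.factorize(genos)[0]
    block_codes = pd.factorize(blocks)[0]
    resid = X - gm[geno_codes] - bm[block_codes] + grand
    scp_e = resid.T @ resid

    mcp_g = scp_g / (g - 1)
    mcp_e = scp_e / ((g - 1) * (r - 1))
    cov_g = (mcp_g - mcp_e) / r
    cov_e = mcp_e
    cov_p = cov_g + cov_e

    def f(m):
        return pd.DataFrame(m, index=traits, columns=traits)

    return CrossProductComponents(
        traits=traits,
        mcp_g=f(mcp_g),
        mcp_e=f(mcp_e),
        cov_g=f(cov_g),
        cov_e=f(cov_e),
        cov_p=f(cov_p),
        n_genotypes=g,
        n_blocks=r,
    )


def correlation_matrices(cpc: CrossProductComponents) -> CorrelationMatrices:
    """Phenotypic and genotypic correlation matrices from the components.

    Traits whose genotypic variance is zero get NaN genotypic
    correlations (excluded with a warning); |r_g| > 1 entries are kept
    as computed and flagged in ``out_of_range_g``.
    """
    traits = cpc.traits
    var_p = np.diag(cpc.cov_p.to_numpy())
    var_g = np.diag(cpc.cov_g.to_numpy())
    if (var_p <= 0).any():
        bad = [t for t, v in zip(traits, var_p) if v <= 0]
        raise DesignError(f"zero phenotypic variance for trait(s): {bad}")

    sd_p = np.sqrt(var_p)
    r_p = cpc.cov_p.to_numpy() / np.outer(sd_p, sd_p)

    with np.errstate(divide="ignore", invalid="ignore"):
        sd_g = np.sqrt(np.where(var_g > 0, var_g, np.nan))
        r_g = cpc.cov_g.to_numpy() / np.outer(sd_g, sd_g)
    np.fill_diagonal(r_p, 1.0)
    np.fill_diagonal(r_g, np.where(var_g > 0, 1.0, np.nan))
    if (var_g <= 0).any():
        bad = [t for t, v in zip(traits, var_g) if v <= 0]
        warnings.warn(
            f"genotypic variance is zero for {bad}; genotypic correlations "
            "set to NaN for those traits",
            stacklevel=2,
        )

    rp_df = pd.DataFrame(r_p, index=traits, columns=traits)
    rg_df = pd.DataFrame(r_g, index=traits, columns=traits)
    mask = rg_df.abs() > 1.0
    if mask.to_numpy().any():
        n = int(mask.to_numpy().sum() // 2)
        warnings.warn(
            f"{n} genotypic correlation(s) exceed |1| (method-of-moments "
            "components); retained unclamped",
            stacklevel=2,
        )
    return CorrelationMatrices(r_p=rp_df, r_g=rg_df, out_of_range_g=mask)


def trait_correlations(
    table: PhenotypeTable, regime, traits=None, year=None
) -> CorrelationMatrices:
    """Convenience: components + correlations for one regime slice."""
    return correlation_matrices(
        cross_product_components(table, traits=traits, year=year, regime=regime)
    )
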
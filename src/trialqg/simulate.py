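"""Synthetic multi-environment RCBD trials with known ground truth.

Every analysis stage in this package can be exercised against data whose
generating parameters are known exactly.  The generator follows the same
general linear model the ANOVA decomposes: for trait t, genotype g, year
y, regime i and block b,

    value = μ_t + regime_shift_{t,i} + year_{t,y} + G_{t,g}
            + (G×I)_{t,g,i} + (G×Y)_{t,g,y} + block_{t,i,b} + ε

with every random term Gaussian at the spec's variance.  Genotype main
effects are multivariate normal across traits through the genetic
correlation matrix, which is how a true genotypic correlation between,
say, fresh and dry yield is induced; residuals are independent across
traits by default (switchable), keeping genotypic and phenotypic
correlation structurally distinct.  Year effects are random draws (years
were a random factor in the emulated trials); regime shifts are fixed.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .genetics import DEFAULT_SELECTION_INTENSITY
from .trial import PhenotypeTable, TrialDesign


@dataclass(frozen=True)
class TraitSpec:
    """Ground-truth parameters for one simulated trait.

    Variances are in trait units²; ``regime_shifts`` maps regime label →
    fixed additive shift (the control regime conventionally has shift 0).
    """

    name: str
    mean: float
    sigma2_g: float
    sigma2_e: float
    regime_shifts: dict = field(default_factory=dict)
    sigma2_year: float = 0.0
    sigma2_gxr: float = 0.0
    sigma2_gxy: float = 0.0
    sigma2_block: float = 0.0

    def __post_init__(self) -> None:
        for label, v in [
            ("sigma2_g", self.sigma2_g), ("sigma2_e", self.sigma2_e),
            ("sigma2_year", self.sigma2_year), ("sigma2_gxr", self.sigma2_gxr),
            ("sigma2_gxy", self.sigma2_gxy), ("sigma2_block", self.sigma2_block),
        ]:
            if v < 0:
                raise SpecError(f"{label} must be non-negative, got {v}")

    # truth for a single year × regime slice, where the effective genotype
    # term is G + G×I + G×Y
    @property
    def slice_sigma2_g(self) -> float:
        return self.sigma2_g + self.sigma2_gxr + self.sigma2_gxy

    def slice_mean(self, regime_shift: float = 0.0) -> float:
        return self.mean + regime_shift

    @property
    def slice_h2(self) -> float:
        s2g = self.slice_sigma2_g
        return 100.0 * s2g / (s2g + self.sigma2_e)


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Design sizes, per-trait truth, genetic correlations and the seed."""

    design: TrialDesign
    traits: tuple
    genetic_correlation: np.ndarray | None = None
    correlated_residuals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if sorted(names) != sorted(self.design.traits):
            raise SpecError(
                f"trait specs {names} do not match design traits {self.design.traits}"
            )
        if self.genetic_correlation is not None:
            R = np.asarray(self.genetic_correlation, float)
            if R.shape != (len(names), len(names)):
                raise SpecError("genetic correlation matrix has wrong shape")
            if not np.allclose(R, R.T):
                raise SpecError("genetic correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0):
                raise SpecError("genetic correlation matrix needs a unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise SpecError("genetic correlation matrix is not positive semidefinite")
            object.__setattr__(self, "genetic_correlation", R)
        object.__setattr__(self, "traits", tuple(self.traits))

    def trait(self, name: str) -> TraitSpec:
        return next(t for t in self.traits if t.name == name)


def _psd_factor(R: np.ndarray) -> np.ndarray:
    """Matrix square root usable for exactly-singular correlation matrices."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_trial(spec: SyntheticTrialSpec, seed: int | None = None) -> PhenotypeTable:
    """Draw one complete balanced trial from the spec's model.

    ``seed`` overrides the spec's own seed (handy for replicate loops);
    the same spec + seed always yields a bit-identical table.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    design = spec.design
    g, r = design.n_genotypes, design.n_blocks
    years, regimes = list(design.years), list(design.regimes)
    ny, ni = len(years), len(regimes)
    order = list(design.traits)
    tspecs = [spec.trait(n) for n in order]
    nt = len(order)

    mu = np.array([t.mean for t in tspecs])
    sd_g = np.sqrt([t.sigma2_g for t in tspecs])
    sd_e = np.sqrt([t.sigma2_e for t in tspecs])
    shifts = np.array(
        [[t.regime_shifts.get(reg, 0.0) for t in tspecs] for reg in regimes]
    )  # ni x nt

    R = (
        spec.genetic_correlation
        if spec.genetic_correlation is not None
        else np.eye(nt)
    )
    F = _psd_factor(R)

    geno = (rng.standard_normal((g, nt)) @ F.T) * sd_g                    # g x t
    year_eff = rng.standard_normal((ny, nt)) * np.sqrt(
        [t.sigma2_year for t in tspecs]
    )
    gxr = rng.standard_normal((g, ni, nt)) * np.sqrt([t.sigma2_gxr for t in tspecs])
    gxy = rng.standard_normal((g, ny, nt)) * np.sqrt([t.sigma2_gxy for t in tspecs])
    block = rng.standard_normal((ni, r, nt)) * np.sqrt(
        [t.sigma2_block for t in tspecs]
    )
    z = rng.standard_normal((ny, ni, g, r, nt))
    if spec.correlated_residuals:
        z = z @ F.T
    resid = z * sd_e

    values = (
        mu[None, None, None, None, :]
        + shifts[None, :, None, None, :]
        + year_eff[:, None, None, None, :]
        + geno[None, None, :, None, :]
        + gxr.transpose(1, 0, 2)[None, :, :, None, :]
        + gxy.transpose(1, 0, 2)[:, None, :, None, :]
        + block[None, :, None, :, :]
        + resid
    )

    idx = pd.MultiIndex.from_product(
        [years, regimes, design.genotype_labels, design.block_labels, order],
        names=["year", "regime", "genotype", "block", "trait"],
    )
    df = pd.DataFrame({"value": values.reshape(-1)}, index=idx).reset_index()
    df = df[["genotype", "year", "regime", "block", "trait", "value"]]
    return PhenotypeTable(df, design=design)


# ---------------------------------------------------------------------------
# Ready-made specs on the scale of a bluegrass drought trial
# ---------------------------------------------------------------------------

def bluegrass_like_spec(
    seed: int = 0,
    n_genotypes: int = 100,
    n_blocks: int = 2,
    yield_correlation: float = 0.95,
    interaction_fraction: float = 0.1,
) -> SyntheticTrialSpec:
    """A four-trait trial on the scale of a 100-ecotype Kentucky
    bluegrass deficit-irrigation evaluation.

    Traits: fresh (FY) and dry (DY) forage yield plus two gas-exchange
    predictors, net photosynthesis rate (A) and stomatal conductance
    (gs).  Control means, genotypic/error variances and the drought
    shifts match a published 100-ecotype panel (FY control GCV ≈ 19.6%,
    slice heritability ≈ 78%, drought loss ≈ 43% by the
    stress-denominator convention); G×regime and G×year variances
    default to 10% of σg² each.  Genetic correlations: strong FY–DY
    (``yield_correlation``), moderate yield–gas-exchange (0.6) and
    strong A–gs (0.8) links, mirroring the co-regulation of stomatal
    conductance and photosynthesis.
    """
    design = TrialDesign(
        n_genotypes=n_genotypes,
        n_blocks=n_blocks,
        years=("2018", "2019"),
        regimes=("control", "drought"),
        traits=("FY", "DY", "A", "gs"),
    )
    ifrac = interaction_fraction

    def trait(name, mu, gcv_pct, h2_pct, stress_mean, year_sd):
        s2g = (gcv_pct / 100.0 * mu) ** 2
        s2p = s2g / (h2_pct / 100.0)
        return TraitSpec(
            name=name,
            mean=mu,
            sigma2_g=s2g,
            sigma2_e=s2p - s2g,
            regime_shifts={"drought": stress_mean - mu},
            sigma2_year=year_sd ** 2,
            sigma2_gxr=ifrac * s2g,
            sigma2_gxy=ifrac * s2g,
            sigma2_block=(0.02 * mu) ** 2,
        )

    # year-effect SDs are kept modest (≈8% of the mean): an additive
    # Gaussian year term cannot mimic the multiplicative year-to-year
    # scaling of real yield data without producing negative yields
    fy = trait("FY", mu=705.0, gcv_pct=19.6, h2_pct=77.7, stress_mean=492.5, year_sd=60.0)
    dy = trait("DY", mu=349.0, gcv_pct=20.0, h2_pct=65.8, stress_mean=280.7, year_sd=30.0)
    a = trait("A", mu=13.0, gcv_pct=6.4, h2_pct=83.9, stress_mean=2.8, year_sd=1.0)
    gs = trait("gs", mu=0.22, gcv_pct=15.8, h2_pct=95.2, stress_mean=0.05, year_sd=0.02)
    q = yield_correlation
    R = np.array(
        [
            [1.0, q,   0.6, 0.6],
            [q,   1.0, 0.6, 0.6],
            [0.6, 0.6, 1.0, 0.8],
            [0.6, 0.6, 0.8, 1.0],
        ]
    )
    return SyntheticTrialSpec(
        design=design, traits=(fy, dy, a, gs), genetic_correlation=R, seed=seed
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def recovery_experiment(
    spec: SyntheticTrialSpec,
    n_replicates: int = 500,
    k: float = DEFAULT_SELECTION_INTENSITY,
    seed: int | None = None,
) -> pd.DataFrame:
    """Estimate pipeline bias by repeated simulation.

    Each replicate draws a fresh trial, runs the RCBD analysis of the
    first year × first regime slice for every trait, and (with ≥ 2
    traits) the genotypic correlation between the first two traits.  The
    report compares the replicate-mean estimates of σg², h², GCV, GA and
    r_g with the spec's truth: bias, SD over replicates, the Monte-Carlo
    standard error of the mean, and whether truth lies inside the ±2
    MC-SE band around the mean (``covered``).

    Also records ``truncated_fraction``: how often σg² was estimated
    negative and truncated (≈ 0.5 when the true σg² is zero).
    """
    if n_replicates < 2:
        raise SpecError("need at least 2 replicates")
    from .anova import rcbd_anova
    from .covcorr import cross_product_components, correlation_matrices
    from .genetics import (
        coefficients_of_variation,
        genetic_advance,
        heritability,
        variance_components,
    )

    design = spec.design
    year0, regime0 = design.years[0], design.regimes[0]
    order = list(design.traits)
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]

    est: dict[tuple, list] = {}
    trunc: dict[str, int] = {t: 0 for t in order}
    rg_vals: list[float] = []
    for rep_seed in child_seeds:
        table = generate_trial(spec, seed=rep_seed)
        for name in order:
            a = rcbd_anova(table, name, year0, regime0)
            vc = variance_components(a)
            trunc[name] += vc.negative_truncated
            if vc.sigma2_p <= 0:
                continue
            h2 = heritability(vc)
            pcv, gcv = coefficients_of_variation(vc, a.grand_mean)
            ga = genetic_advance(vc, h2, k=k)
            for param, val in [
                ("sigma2_g", vc.sigma2_g), ("h2", h2), ("gcv", gcv), ("ga", ga),
            ]:
                est.setdefault((name, param), []).append(val)
        if len(order) >= 2:
            cpc = cross_product_components(
                table, traits=order[:2], year=year0, regime=regime0
            )
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                cm = correlation_matrices(cpc)
            rg = cm.r_g.iloc[0, 1]
            if np.isfinite(rg):
                rg_vals.append(float(rg))

    rows = []

    def truth_row(name, param):
        t = spec.trait(name)
        shift = t.regime_shifts.get(regime0, 0.0)
        mu = t.slice_mean(shift)
        s2g, s2e = t.slice_sigma2_g, t.sigma2_e
        h2 = t.slice_h2
        if param == "sigma2_g":
            return s2g
        if param == "h2":
            return h2
        if param == "gcv":
            return 100.0 * np.sqrt(s2g) / mu
        if param == "ga":
            return k * np.sqrt(s2g + s2e) * h2 / 100.0
        raise KeyError(param)

    for (name, param), vals in est.items():
        v = np.asarray(vals)
        truth = truth_row(name, param)
        mean, sd = v.mean(), v.std(ddof=1)
        mc_se = sd / np.sqrt(len(v))
        rows.append(
            dict(
                trait=name, parameter=param, truth=truth, mean=mean,
                bias=mean - truth, sd=sd, mc_se=mc_se,
                covered=abs(mean - truth) <= 2 * mc_se,
                n=len(v),
            )
        )
    if rg_vals:
        t0, t1 = spec.trait(order[0]), spec.trait(order[1])
        R = spec.genetic_correlation
        rho = 1.0 if R is None else float(R[0, 1])
        cov = rho * np.sqrt(t0.sigma2_g * t1.sigma2_g)
        truth = cov / np.sqrt(t0.slice_sigma2_g * t1.slice_sigma2_g)
        v = np.asarray(rg_vals)
        mean, sd = v.mean(), v.std(ddof=1)
        mc_se = sd / np.sqrt(len(v))
        rows.append(
            dict(
                trait=f"{order[0]}:{order[1]}", parameter="r_g", truth=truth,
                mean=mean, bias=mean - truth, sd=sd, mc_se=mc_se,
                covered=abs(mean - truth) <= 2 * mc_se, n=len(v),
            )
        )
    for name, count in trunc.items():
        rows.append(
            dict(
                trait=name, parameter="truncated_fraction",
                truth=np.nan, mean=count / n_replicates, bias=np.nan,
                sd=np.nan, mc_se=np.nan, covered=True, n=n_replicates,
            )
        )
    return pd.DataFrame(rows)


def single_environment_spec(
    n_genotypes: int = 100,
    n_blocks: int = 2,
    mean: float = 100.0,
    sigma2_g: float = 40.0,
    sigma2_e: float = 20.0,
    genetic_correlation: float | None = None,
    n_traits: int = 1,
    seed: int = 0,
) -> SyntheticTrialSpec:
    """Minimal one-year one-regime spec for estimator recovery studies."""
    names = ["T1", "T2", "T3"][:n_traits] if n_traits <= 3 else [
        f"T{i+1}" for i in range(n_traits)
    ]
    design = TrialDesign(
        n_genotypes=n_genotypes,
        n_blocks=n_blocks,
        years=("Y1",),
        regimes=("control",),
        traits=tuple(names),
    )
    traits = tuple(
        TraitSpec(name=n, mean=mean, sigma2_g=sigma2_g, sigma2_e=sigma2_e)
        for n in names
    )
    R = None
    if genetic_correlation is not None and n_traits >= 2:
        R = np.full((n_traits, n_traits), genetic_correlation)
        np.fill_diagonal(R, 1.0)
    return SyntheticTrialSpec(design=design, traits=traits, genetic_correlation=R, seed=seed)
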
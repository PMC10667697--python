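"""Variance components and selection-response statistics.

From a balanced RCBD ANOVA with expected mean squares
E[MS_g] = σe² + r σg² and E[MS_e] = σe², the method-of-moments
components are

    σg² = (MS_g − MS_e) / r,    σe² = MS_e,    σp² = σg² + σe².

On top of these the package computes the standard breeders' summary for
each trait × regime × year:

    GCV = 100 σg / μ,  PCV = 100 σp / μ          (coefficients of variation)
    h²  = 100 σg² / σp²                          (broad-sense heritability, %)
    GA  = k σp h²/100                            (genetic advance per cycle)
    GAM = 100 GA / μ                             (advance as % of mean)

with selection intensity k = 2.063 (top 5% selected).  GA multiplies the
selection differential on the phenotypic-SD scale by heritability — the
textbook response to truncation selection.  Some sources print the
formula with the error SD instead of the phenotypic SD; that variant
does not satisfy GA = k·σp·h²/100 consistency with published trial
tables and is available only behind ``strict_printed_form``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .anova import AnovaTable
from .errors import DesignError, DomainError
from .trial import PhenotypeTable

#: standardized selection differential for a 5% selected proportion
DEFAULT_SELECTION_INTENSITY = 2.063

#: Burton-style cutoffs (%) for labelling coefficients of variation
CV_CLASS_BOUNDS = (10.0, 20.0)


@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic, error and phenotypic variances in trait units²."""

    sigma2_g: float
    sigma2_e: float
    negative_truncated: bool = False

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e


@dataclass(frozen=True)
class GeneticSummary:
    """One row of the per-trait genetic summary (a trait × regime × year)."""

    trait: str
    year: str
    regime: str
    mean: float
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    gcv: float
    pcv: float
    h2: float
    ga: float
    gam: float
    k: float = DEFAULT_SELECTION_INTENSITY
    negative_truncated: bool = False


def variance_components(a: AnovaTable) -> VarianceComponents:
    """Method-of-moments components from the RCBD expected mean squares.

    A negative genotypic estimate (MS_g < MS_e, common when the true
    σg² is near zero) is truncated to 0 and flagged.
    """
    r = a.n_blocks
    if r <= 0:
        raise DesignError("number of blocks must be positive")
    sigma2_g = (a.ms_genotype - a.ms_error) / r
    truncated = sigma2_g < 0
    return VarianceComponents(
        sigma2_g=max(sigma2_g, 0.0),
        sigma2_e=a.ms_error,
        negative_truncated=truncated,
    )


def coefficients_of_variation(
    vc: VarianceComponents, mean: float
) -> tuple[float, float]:
    """(PCV %, GCV %): phenotypic and genotypic SD as a percent of the mean."""
    if mean <= 0:
        raise DomainError("coefficients of variation need a positive mean")
    pcv = 100.0 * math.sqrt(vc.sigma2_p) / mean
    gcv = 100.0 * math.sqrt(vc.sigma2_g) / mean
    return pcv, gcv


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability in percent: 100 σg²/σp².

    Identically equals 100 (GCV/PCV)² whenever both are defined.
    """
    if vc.sigma2_p <= 0:
        raise DomainError("heritability undefined: phenotypic variance is zero")
    return 100.0 * vc.sigma2_g / vc.sigma2_p


def heritability_from_cv(gcv: float, pcv: float) -> float:
    """h² (%) from the identity 100·(GCV/PCV)² — useful when only the
    coefficients of variation of a published summary are available."""
    if pcv <= 0:
        raise DomainError("PCV must be positive")
    return 100.0 * (gcv / pcv) ** 2


def genetic_advance(
    vc: VarianceComponents,
    h2: float,
    k: float = DEFAULT_SELECTION_INTENSITY,
    strict_printed_form: bool = False,
) -> float:
    """Expected gain per cycle of truncation selection, GA = k σp h²/100.

    ``strict_printed_form`` swaps σp for σe (a variant that appears in
    some printed formulas but is inconsistent with published GA values).
    """
    sd = math.sqrt(vc.sigma2_e if strict_printed_form else vc.sigma2_p)
    return k * sd * h2 / 100.0


def genetic_advance_from_summary(
    pcv: float,
    mean: float,
    h2: float,
    k: float = DEFAULT_SELECTION_INTENSITY,
) -> float:
    """GA reconstructed from a published summary row: σp = PCV·μ/100."""
    if mean <= 0:
        raise DomainError("mean must be positive")
    sigma_p = pcv * mean / 100.0
    return k * sigma_p * h2 / 100.0


def genetic_advance_percent(ga: float, mean: float) -> float:
    """Genetic advance as a percentage of the trait mean, GAM = 100 GA/μ."""
    if mean <= 0:
        raise DomainError("GAM needs a positive mean")
    return 100.0 * ga / mean


def percent_reduction(
    mean_control: float, mean_stress: float, denominator: str = "stress"
) -> float:
    """Percent loss under stress relative to the chosen denominator.

    The default expresses the loss relative to the *stress* mean,
    100·(control − stress)/stress, the convention used when a trial
    reports how much larger the well-watered mean is; ``"control"``
    gives the usual relative-change form 100·(control − stress)/control.
    """
    if denominator not in {"stress", "control"}:
        raise ValueError("denominator must be 'stress' or 'control'")
    denom = mean_stress if denominator == "stress" else mean_control
    if denom <= 0:
        raise DomainError("denominator mean must be positive")
    return 100.0 * (mean_control - mean_stress) / denom


def classify_cv(cv: float, bounds: tuple[float, float] = CV_CLASS_BOUNDS) -> str:
    """Label a GCV/PCV value low/moderate/high by the Burton-style cutoffs."""
    lo, hi = bounds
    if cv < lo:
        return "low"
    if cv <= hi:
        return "moderate"
    return "high"


def genetic_summary(
    a: AnovaTable,
    k: float = DEFAULT_SELECTION_INTENSITY,
    strict_printed_form: bool = False,
) -> GeneticSummary:
    """Full breeders' summary for one trait × environment-year ANOVA."""
    vc = variance_components(a)
    mean = a.grand_mean
    pcv, gcv = coefficients_of_variation(vc, mean)
    h2 = heritability(vc)
    ga = genetic_advance(vc, h2, k=k, strict_printed_form=strict_printed_form)
    gam = genetic_advance_percent(ga, mean)
    return GeneticSummary(
        trait=a.trait,
        year=a.year,
        regime=a.regime,
        mean=mean,
        sigma2_g=vc.sigma2_g,
        sigma2_e=vc.sigma2_e,
        sigma2_p=vc.sigma2_p,
        gcv=gcv,
        pcv=pcv,
        h2=h2,
        ga=ga,
        gam=gam,
        k=k,
        negative_truncated=vc.negative_truncated,
    )


def summarize_trial(
    table: PhenotypeTable,
    k: float = DEFAULT_SELECTION_INTENSITY,
    strict_printed_form: bool = False,
) -> pd.DataFrame:
    """Genetic summary rows for every trait × year × regime in the table."""
    from .anova import rcbd_anova

    rows = []
    for trait in table.traits:
        for year in table.years:
            for regime in table.regimes:
                a = rcbd_anova(table, trait, year, regime)
                s = genetic_summary(a, k=k, strict_printed_form=strict_printed_form)
                rows.append(vars(s))
    return pd.DataFrame(rows)
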
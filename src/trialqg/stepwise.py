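"""Forward stepwise least-squares regression with backward checks.

The classic variable-selection procedure used to rank physiological
predictors of a response trait: at each step the candidate with the
largest partial F enters if its p-value is below ``alpha_enter``; after
every entry, any included variable whose p-value has risen above
``alpha_stay`` is removed.  The procedure stops when no entry or removal
changes the model.  Partial R² of a step is the increment in model R²,
so the cumulative column is non-decreasing and the final cumulative R²
equals the R² of a direct fit on the selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DesignError
from .trial import PhenotypeTable

#: historical default entry/stay significance levels
DEFAULT_ALPHA = 0.15

#: condition-number guard for near-collinear candidates
CONDITION_LIMIT = 1e8


@dataclass
class StepwiseResult:
    """Entry/removal trace and the final fitted model."""

    steps: pd.DataFrame  # step, action, variable, estimate, partial_r2, model_r2, F, p
    selected: list[str]
    intercept: float
    coefficients: pd.Series
    model_r2: float
    final_fit: object = field(repr=False, default=None)


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    alpha_enter: float = DEFAULT_ALPHA,
    alpha_stay: float = DEFAULT_ALPHA,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward stepwise with backward elimination on ordinary least squares.

    Parameters
    ----------
    response :
        n observations of the response trait.
    predictors :
        n × p candidate predictor matrix (one column per trait).
    alpha_enter, alpha_stay :
        Significance thresholds for entry and retention.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise DesignError(f"need more than {p + 2} observations, got {n}")
    if (X.std(axis=0) == 0).any():
        const = list(X.columns[X.std(axis=0) == 0])
        raise DesignError(f"constant predictor(s): {const}")

    selected: list[str] = []
    skipped: set[str] = set()
    trace: list[dict] = []
    prev_r2 = 0.0

    for step in range(1, max_steps + 1):
        changed = False
        # --- forward: best candidate by partial F ---
        candidates = [c for c in X.columns if c not in selected and c not in skipped]
        best = None
        for c in candidates:
            cols = selected + [c]
            design = sm.add_constant(X[cols], has_constant="add")
            if np.linalg.cond(design.to_numpy()) > CONDITION_LIMIT:
                warnings.warn(
                    f"predictor {c!r} is near-collinear with the current model; skipped",
                    stacklevel=2,
                )
                skipped.add(c)
                continue
            fit = _fit(y, X[cols])
            fval = fit.tvalues[c] ** 2
            pval = fit.pvalues[c]
            if best is None or fval > best[1]:
                best = (c, float(fval), float(pval), fit)
        if best is not None and best[2] < alpha_enter:
            c, fval, pval, fit = best
            selected.append(c)
            r2 = float(fit.rsquared)
            trace.append(
                {
                    "step": step,
                    "action": "enter",
                    "variable": c,
                    "estimate": float(fit.params[c]),
                    "partial_r2": r2 - prev_r2,
                    "model_r2": r2,
                    "F": fval,
                    "p": pval,
                }
            )
            prev_r2 = r2
            changed = True

        # --- backward: drop anything above alpha_stay ---
        while selected:
            fit = _fit(y, X[selected])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] <= alpha_stay:
                break
            selected.remove(worst)
            r2 = float(_fit(y, X[selected]).rsquared) if selected else 0.0
            trace.append(
                {
                    "step": step,
                    "action": "remove",
                    "variable": worst,
                    "estimate": np.nan,
                    "partial_r2": r2 - prev_r2,
                    "model_r2": r2,
                    "F": float(fit.tvalues[worst] ** 2),
                    "p": float(pvals[worst]),
                }
            )
            prev_r2 = r2
            changed = True

        if not changed:
            break

    if selected:
        final = _fit(y, X[selected])
        coefs = final.params.drop("const")
        intercept = float(final.params["const"])
        model_r2 = float(final.rsquared)
    else:
        final = None
        coefs = pd.Series(dtype=float)
        intercept = float(y.mean())
        model_r2 = 0.0

    steps = pd.DataFrame(
        trace,
        columns=["step", "action", "variable", "estimate",
                 "partial_r2", "model_r2", "F", "p"],
    )
    return StepwiseResult(
        steps=steps,
        selected=selected,
        intercept=intercept,
        coefficients=coefs,
        model_r2=model_r2,
        final_fit=final,
    )


def yield_regression(
    table: PhenotypeTable,
    response_trait: str,
    predictor_traits,
    regime,
    year=None,
    alpha_enter: float = DEFAULT_ALPHA,
    alpha_stay: float = DEFAULT_ALPHA,
) -> StepwiseResult:
    """Stepwise fit of a yield trait on physiological traits, per regime.

    Observations are genotype means within the regime (years and blocks
    pooled unless ``year`` is given), matching the one-model-per-regime
    layout of published trait-association tables.
    """
    means = table.genotype_means(regime=regime, year=year)
    missing = [t for t in [response_trait, *predictor_traits] if t not in means]
    if missing:
        raise DesignError(f"trait(s) not in table: {missing}")
    return stepwise_regression(
        means[response_trait],
        means[list(predictor_traits)],
        alpha_enter=alpha_enter,
        alpha_stay=alpha_stay,
    )
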
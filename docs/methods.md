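# Methods

## The trial model

The analysis substrate is a balanced multi-environment RCBD: g genotypes
(accessions) each appearing once in every one of r complete blocks,
blocks nested within irrigation regime, and the whole layout repeated
across years. Per trait and year × regime slice the working model is the
classical two-way decomposition

    y_ij = μ + g_i + b_j + e_ij,

from which the ANOVA gives MS_genotype and MS_error with the expected
mean squares E[MS_g] = σe² + r·σg² and E[MS_e] = σe². Years are treated
as random and regime and accession as fixed; these roles are recorded as
metadata and affect only F-test denominators, never sums of squares.

## Variance components and selection response

Method-of-moments inversion of the expected mean squares:

    σ̂g² = (MS_g − MS_e)/r,   σ̂e² = MS_e,   σ̂p² = σ̂g² + σ̂e².

A negative σ̂g² (MS_g < MS_e, probability ≈ ½ when the true σg² is 0) is
truncated to zero and flagged; downstream statistics use the truncated
value. On top of the components:

- GCV = 100·σ̂g/μ and PCV = 100·σ̂p/μ, with μ the slice grand mean.
  Burton-style verbal classes (<10 low, 10–20 moderate, >20 high) are
  available and configurable.
- Broad-sense heritability h² = 100·σ̂g²/σ̂p², identically equal to
  100·(GCV/PCV)² — an identity the test suite asserts to 1e−12.
- Genetic advance GA = k·σ̂p·h²/100 with selection intensity k = 2.063
  (top 5% selected), i.e. the selection differential on the phenotypic-SD
  scale times heritability; GAM = 100·GA/μ.

Some printed sources give the genetic-advance formula with the *error*
SD in place of the phenotypic SD. That variant is inconsistent with the
GA values of published summary tables (reconstructing the bundled trial's
FY 2018 control row with σp reproduces the printed 251.19 within 0.2%;
σe does not come close), so the phenotypic-SD form is the default and the
error-SD variant sits behind `strict_printed_form=True`.

Percent drought loss defaults to the stress-denominator convention,
100·(control − stress)/stress, because that is the convention under
which the bundled trial's printed integer losses (43/46% FY, 24/29% DY)
are recovered from its printed means; the control-denominator form is an
option.

Note that the plug-in ratio estimators are consistent but not unbiased:
at g = 100, r = 2 the Monte-Carlo mean of ĥ² sits ≈ 0.4 percentage
points below the generating ratio (a Jensen effect of order 1/g). The
recovery tests therefore compare simulation means against the exact
finite-sample expectation of the estimator — computable independently
because MS_g and MS_e are independent scaled χ² variables in a balanced
normal RCBD — and separately bound the bias against truth at 1%.

## Combined ANOVA

The two-year × two-regime table uses the split-plot-in-time layout with
blocks nested in regime: sources Ir, Error I = R(M), G, Ir×G,
Error II = R×G(M), Y, Y×Ir, Y×G, Y×G×Ir, and a pooled Residual
(= Y×R(M) + Y×G×R(M)). All SS come from marginal means of the balanced
layout, so they are exact; the residual is obtained by subtraction and
clamped at 0 against roundoff. For g = 100, r = 2 the df column is
(1, 2, 99, 99, 198, 1, 1, 99, 99, 200), summing to 799.

F-test denominators are a documented convention (the source tables this
mirrors do not state them): Ir against Error I; G and Ir×G against
Error II; all year-containing terms against the Residual. Variance
components for the genetic summary always come from the per-slice RCBD
tables, not the combined table, because summary statistics are reported
per regime per year.

## Correlations from mean cross-products

For each trait pair the genotype and error mean cross-products (MCP) of
the same balanced layout give, by analogy with the univariate components,

    Cov_g = (MCP_g − MCP_e)/r,  Cov_e = MCP_e,  Cov_p = Cov_g + Cov_e,

and correlations r_p = Cov_p/(σp(X)σp(Y)), r_g = Cov_g/(σg(X)σg(Y)).
Cov_p is a positively weighted sum of two PSD matrices, so |r_p| ≤ 1
always; r_g, built from method-of-moments components, can exceed |1| and
is then flagged and reported unclamped (clamping happens only in the
plotting layer). In a balanced layout r_p equals the plain Pearson
correlation of plot values after sweeping out block effects — the test
suite uses that as an independent oracle.

Per-regime matrices pool years by averaging each genotype × block cell
over years before the cross-product analysis; a per-year option exists.
The pooling rule is a package choice (the emulated workflow reports one
matrix per regime without stating its pooling).

## Stepwise regression

Classic forward selection with backward checks on ordinary least squares
(statsmodels OLS underneath): the candidate with the largest partial F
enters while p < α_enter (default 0.15), entered variables with
p > α_stay (default 0.15) leave, and the procedure stops when a full
pass changes nothing. Partial R² of a step is the increment of model R²,
so the cumulative column is non-decreasing and ends at the direct-fit R²
of the selected set (asserted to 1e−10). Near-collinear candidates
(design condition number > 1e8) are skipped with a warning.
Observations default to genotype means per regime, years pooled.

## Clustering

Genotype × trait mean matrices are z-scored per trait (the panel mixes
g/plot with µmol m⁻² s⁻¹ and unitless ratios; unscaled distances would
be dominated by yield), then clustered with Ward's criterion applied to
Manhattan distances under the squared-dissimilarity Lance–Williams
update — the ward.D2 convention. scipy's `linkage(..., method="ward")`
on a precomputed condensed matrix implements exactly that recurrence; an
exhaustive pairwise-merge oracle in the tests confirms merge order and
heights. Cutting the tree at n groups (default 3) labels groups by
descending mean standardized profile, so group I is always the
high-performing set.

## Synthetic trials

The generator draws from the same linear model the ANOVA decomposes:
fixed trait means and regime shifts; Gaussian random year, genotype,
G×regime, G×year, block-within-regime and residual effects at the
spec's variances; genotype main effects multivariate normal across
traits through a genetic correlation matrix (validated symmetric PSD
with unit diagonal). Residuals are independent across traits by default
(switchable), keeping genotypic and phenotypic correlation structurally
distinct. Everything is reproducible bit-for-bit under the spec seed.

The ready-made `bluegrass_like_spec` mirrors a 100-ecotype panel:
g = 100, r = 2, two years, two regimes, four traits (FY, DY, A, gs) with
means, GCVs, heritabilities and drought shifts taken from the bundled
published summary's 2018 control rows (FY: μ = 705, GCV 19.6%,
h² 77.7%, drought shift −212.5 giving ≈ 43% loss by the
stress-denominator convention), G×regime and G×year variances at 10% of
σg², block SD at 2% of the mean, and genetic correlations 0.95 (FY–DY),
0.6 (yield–gas exchange) and 0.8 (A–gs).

What the generator deliberately does not emulate: the strong
*multiplicative* year-to-year scaling of real yield trials (the additive
Gaussian year term is kept at SD ≈ 8% of the mean, because an additive
term at the observed ≈ 2× swing would produce negative yields and
distort stress/control ratios); regime-dependent variance changes
(variances are constant across regimes, whereas real drought data often
show inflated CVs under stress); spatial field trend; and non-Gaussian
traits. Passing recovery tests therefore demonstrate estimator
correctness under the stated GLM, not robustness to those departures.

Each year × regime slice analysed in isolation sees the genotype effect
G + G×regime + G×year, so slice-level truth for recovery experiments is
σg²(slice) = σg² + σg×r² + σg×y², with the genetic correlation diluted
accordingly; `TraitSpec.slice_sigma2_g`/`slice_h2` expose those values.

## Problem sizes and numerics

Recovery experiments default to 500 replicates of a g = 100, r = 2
single-slice trial (seconds of runtime); convergence of the simulated
genotype-effect variance is checked at g = 2000 within 5%. Residual SS
in both ANOVA paths are clamped at zero against floating-point
subtraction noise; oracle-equivalence tests run at 1e−9 relative
tolerance. Comparisons against the bundled published summary use
tolerances that account for the two-decimal rounding of its printed
inputs (first-order propagation of ±0.005 on GCV/PCV, which exceeds
±0.1 on h² for the low-CV traits). Degenerate inputs — zero phenotypic
variance, non-positive means, stress means ≤ 0 — raise typed domain
errors rather than returning NaN.

## Configuration surface

Selection intensity k (default 2.063), stepwise α_enter/α_stay (0.15),
cluster group count (3) and scaling policy (z-score), correlation
pooling (per regime), percent-reduction denominator (stress), CV class
bounds (10/20%) and the strict printed GA form are all exposed as
function arguments, CLI flags, and YAML config keys.
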
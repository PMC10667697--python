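import numpy as np
import pandas as pd
import pytest

from trialqg import (
    DesignError,
    PhenotypeTable,
    combined_anova,
    combined_df_vector,
    generate_trial,
    rcbd_anova,
    single_environment_spec,
)

from conftest import long_frame, random_balanced_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_rcbd_ss(arr):
    """SS by direct summation over means — no matrix shortcuts."""
    arr = np.asarray(arr, float)
    g, r = arr.shape
    grand = arr.mean()
    ss_g = sum(r * (arr[i].mean() - grand) ** 2 for i in range(g))
    ss_b = sum(g * (arr[:, j].mean() - grand) ** 2 for j in range(r))
    ss_t = sum((arr[i, j] - grand) ** 2 for i in range(g) for j in range(r))
    return ss_g, ss_b, ss_t - ss_g - ss_b


def statsmodels_rcbd_ss(arr):
    """Cross-check with an OLS two-way ANOVA fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    arr = np.asarray(arr, float)
    g, r = arr.shape
    df = pd.DataFrame(
        {
            "y": arr.ravel(),
            "geno": np.repeat([f"g{i}" for i in range(g)], r),
            "blk": np.tile([f"b{j}" for j in range(r)], g),
        }
    )
    fit = ols("y ~ C(geno) + C(blk)", df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return (
        tab.loc["C(geno)", "sum_sq"],
        tab.loc["C(blk)", "sum_sq"],
        tab.loc["Residual", "sum_sq"],
    )


def brute_force_combined_ss(y):
    """Combined factorial SS by explicit loops; y[year, regime, geno, block]."""
    ny, ni, ng, nr = y.shape
    grand = y.mean()
    out = {}
    out["Ir"] = sum(
        ny * ng * nr * (y[:, i].mean() - grand) ** 2 for i in range(ni)
    )
    out["Error I"] = sum(
        ny * ng * (y[:, i, :, b].mean() - y[:, i].mean()) ** 2
        for i in range(ni)
        for b in range(nr)
    )
    out["G"] = sum(
        ny * ni * nr * (y[:, :, k].mean() - grand) ** 2 for k in range(ng)
    )
    out["Ir x G"] = sum(
        ny * nr
        * (y[:, i, k].mean() - y[:, i].mean() - y[:, :, k].mean() + grand) ** 2
        for i in range(ni)
        for k in range(ng)
    )
    out["Error II"] = sum(
        ny
        * (
            y[:, i, k, b].mean()
            - y[:, i, k].mean()
            - y[:, i, :, b].mean()
            + y[:, i].mean()
        )
        ** 2
        for i in range(ni)
        for k in range(ng)
        for b in range(nr)
    )
    out["Y"] = sum(
        ni * ng * nr * (y[a].mean() - grand) ** 2 for a in range(ny)
    )
    out["Y x Ir"] = sum(
        ng * nr
        * (y[a, i].mean() - y[a].mean() - y[:, i].mean() + grand) ** 2
        for a in range(ny)
        for i in range(ni)
    )
    out["Y x G"] = sum(
        ni * nr
        * (y[a, :, k].mean() - y[a].mean() - y[:, :, k].mean() + grand) ** 2
        for a in range(ny)
        for k in range(ng)
    )
    out["Y x G x Ir"] = sum(
        nr
        * (
            y[a, i, k].mean()
            - y[a, i].mean()
            - y[a, :, k].mean()
            - y[:, i, k].mean()
            + y[a].mean()
            + y[:, i].mean()
            + y[:, :, k].mean()
            - grand
        )
        ** 2
        for a in range(ny)
        for i in range(ni)
        for k in range(ng)
    )
    ss_total = ((y - grand) ** 2).sum()
    out["Residual"] = ss_total - sum(out.values())
    return out


def _table_from_cube(y):
    ny, ni, ng, nr = y.shape
    vals = {
        (f"Y{a+1}", f"R{i+1}", "T"): y[a, i]
        for a in range(ny)
        for i in range(ni)
    }
    return PhenotypeTable(
        long_frame(
            vals,
            years=[f"Y{a+1}" for a in range(ny)],
            regimes=[f"R{i+1}" for i in range(ni)],
        )
    )


# ---------------------------------------------------------------------------
# per-environment RCBD
# ---------------------------------------------------------------------------

class TestRcbdAnova:
    def test_constant_data_has_zero_ss(self):
        table = PhenotypeTable(long_frame({"T": np.full((3, 2), 7.0)}))
        a = rcbd_anova(table, "T", "Y1", "R1")
        assert (a.table["SS"] == 0).all()

    def test_matches_brute_force_on_toy(self, toy_table):
        a = rcbd_anova(toy_table, "T", "Y1", "R1")
        arr = [[10.0, 12.0], [14.0, 13.0], [20.0, 23.0]]
        ss_g, ss_b, ss_e = brute_force_rcbd_ss(arr)
        assert a.table.loc["genotype", "SS"] == pytest.approx(ss_g, rel=1e-12)
        assert a.table.loc["block", "SS"] == pytest.approx(ss_b, rel=1e-12)
        assert a.table.loc["error", "SS"] == pytest.approx(ss_e, rel=1e-12)
        assert a.table.loc["genotype", "df"] == 2
        assert a.table.loc["error", "df"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        g, r = rng.integers(2, 6), rng.integers(2, 5)
        arr = rng.normal(100, 15, size=(g, r))
        table = PhenotypeTable(long_frame({"T": arr}))
        a = rcbd_anova(table, "T", "Y1", "R1")
        for val, ref in zip(
            a.table["SS"], np.array(brute_force_rcbd_ss(arr))[[1, 0, 2]]
        ):
            assert val == pytest.approx(ref, rel=1e-9, abs=1e-9)
        sm_g, sm_b, sm_e = statsmodels_rcbd_ss(arr)
        assert a.table.loc["genotype", "SS"] == pytest.approx(sm_g, rel=1e-8)
        assert a.table.loc["block", "SS"] == pytest.approx(sm_b, rel=1e-8)
        assert a.table.loc["error", "SS"] == pytest.approx(sm_e, rel=1e-8)

    def test_genotype_label_permutation_leaves_ss_unchanged(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(10, 2, size=(5, 3))
        t1 = PhenotypeTable(long_frame({"T": arr}))
        t2 = PhenotypeTable(long_frame({"T": arr[rng.permutation(5)]}))
        a1 = rcbd_anova(t1, "T", "Y1", "R1")
        a2 = rcbd_anova(t2, "T", "Y1", "R1")
        np.testing.assert_allclose(a1.table["SS"], a2.table["SS"], rtol=1e-12)

    def test_shift_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(4, 3))
        base = rcbd_anova(PhenotypeTable(long_frame({"T": arr})), "T", "Y1", "R1")
        shifted = rcbd_anova(
            PhenotypeTable(long_frame({"T": arr + 123.0})), "T", "Y1", "R1"
        )
        scaled = rcbd_anova(
            PhenotypeTable(long_frame({"T": 2.5 * arr})), "T", "Y1", "R1"
        )
        np.testing.assert_allclose(base.table["SS"], shifted.table["SS"], atol=1e-9)
        np.testing.assert_allclose(
            scaled.table["SS"], 2.5**2 * base.table["SS"], rtol=1e-10
        )

    def test_unbalanced_subset_is_design_error(self):
        df = long_frame({"T": [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]}).iloc[:-1]
        with pytest.warns(UserWarning):
            table = PhenotypeTable(df)
        with pytest.raises(DesignError, match="missing"):
            rcbd_anova(table, "T", "Y1", "R1")

    def test_single_genotype_is_design_error(self):
        table = PhenotypeTable(long_frame({"T": [[1.0, 2.0]]}))
        with pytest.raises(DesignError):
            rcbd_anova(table, "T", "Y1", "R1")

    def test_null_genotypic_signal_equalises_mean_squares(self):
        """With sigma_g2 = 0, E[MS_g] = E[MS_e]: the mean difference over
        many simulated trials is statistically zero."""
        spec = single_environment_spec(
            n_genotypes=15, n_blocks=3, sigma2_g=0.0, sigma2_e=4.0, n_traits=1
        )
        diffs = []
        for seed in range(400):
            table = generate_trial(spec, seed=seed)
            a = rcbd_anova(table, "T1", "Y1", "control")
            diffs.append(a.ms_genotype - a.ms_error)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se


# ---------------------------------------------------------------------------
# combined ANOVA
# ---------------------------------------------------------------------------

class TestCombinedAnova:
    def test_df_vector_matches_published_design(self):
        assert combined_df_vector(100, 2, 2, 2) == (
            1, 2, 99, 99, 198, 1, 1, 99, 99, 200,
        )

    def test_total_df_is_cells_minus_one(self):
        assert sum(combined_df_vector(100, 2, 2, 2)) == 2 * 2 * 2 * 100 - 1

    def test_engine_df_agree_with_bookkeeping(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(2, 2, 6, 2))
        c = combined_anova(_table_from_cube(y), "T")
        assert c.df_vector == combined_df_vector(6, 2, 2, 2)

    def test_constant_data_has_zero_ss(self):
        y = np.full((2, 2, 4, 2), 3.0)
        c = combined_anova(_table_from_cube(y), "T")
        assert (c.table["SS"] == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_ss_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(20, 4, size=(2, 2, 5, 2))
        c = combined_anova(_table_from_cube(y), "T")
        oracle = brute_force_combined_ss(y)
        for src, ref in oracle.items():
            assert c.table.loc[src, "SS"] == pytest.approx(
                ref, rel=1e-9, abs=1e-9
            ), src
        assert c.table["SS"].sum() == pytest.approx(
            ((y - y.mean()) ** 2).sum(), rel=1e-12
        )

    def test_single_year_is_design_error(self):
        rng = np.random.default_rng(1)
        table = random_balanced_table(rng, g=3, r=2, regimes=("R1", "R2"))
        with pytest.raises(DesignError, match="years"):
            combined_anova(table, "X")

    def test_f_tests_use_convention_denominators(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(2, 2, 6, 2))
        c = combined_anova(_table_from_cube(y), "T").table
        assert c.loc["Ir", "F"] == pytest.approx(
            c.loc["Ir", "MS"] / c.loc["Error I", "MS"]
        )
        assert c.loc["G", "F"] == pytest.approx(
            c.loc["G", "MS"] / c.loc["Error II", "MS"]
        )
        assert c.loc["Y x G", "F"] == pytest.approx(
            c.loc["Y x G", "MS"] / c.loc["Residual", "MS"]
        )
        assert np.isnan(c.loc["Error I", "F"])
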
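from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import stagedex as sx
from stagedex.linmod import DesignMatrix, LinModError, moderated_variance

from conftest import bh_step_up_oracle


def random_dataset(rng, n_genes, groups):
    cols = [f"TCGA-{i:05d}{'11' if g == 'control' else '01'}A" for i, g in enumerate(groups)]
    frame = pd.DataFrame(
        rng.normal(size=(n_genes, len(groups))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return sx.ExpressionDataset(frame, pd.Series(list(groups), index=cols, dtype=object))


class TestBuildDesign:
    def test_numeric_codes(self):
        d = sx.build_design(["control", "I", "II", "III", "IV"], "numeric")
        assert d.matrix[:, 1].tolist() == [0.0, 1.0, 2.0, 3.0, 4.0]
        assert d.matrix[:, 0].tolist() == [1.0] * 5

    def test_all_control_baseline_has_zero_stage_columns(self):
        d = sx.build_design(["control"] * 4, "baseline")
        assert np.all(d.matrix[:, 1:] == 0)
        assert np.all(d.matrix[:, 0] == 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown sample group"):
            sx.build_design(["control", "V"], "cellmeans")

    def test_unknown_kind_rejected(self):
        with pytest.raises(LinModError):
            sx.build_design(["control"], "fancy")

    def test_baseline_and_cellmeans_give_identical_fitted_values(self):
        rng = np.random.default_rng(1)
        groups = ["control"] * 4 + ["I"] * 3 + ["II"] * 3 + ["III"] * 3 + ["IV"] * 3
        ds = random_dataset(rng, 20, groups)
        f1 = sx.fit_gene_models(ds, sx.build_design(ds.groups, "baseline"))
        f2 = sx.fit_gene_models(ds, sx.build_design(ds.groups, "cellmeans"))
        assert np.allclose(f1.fitted_values(), f2.fitted_values(), atol=1e-10)


class TestFitGeneModels:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        groups = ["control"] * 4 + ["I"] * 4 + ["II"] * 4 + ["III"] * 4 + ["IV"] * 4
        ds = random_dataset(rng, 15, groups)
        design = sx.build_design(ds.groups, "baseline")
        fits = sx.fit_gene_models(ds, design)
        X = design.matrix
        for g in range(15):
            y = ds.values.iloc[g].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fits.coefficients[g], beta, atol=1e-10)

    def test_cellmeans_coefficients_are_group_means(self):
        rng = np.random.default_rng(3)
        groups = ["control"] * 3 + ["I"] * 5 + ["II"] * 2 + ["III"] * 4 + ["IV"] * 2
        ds = random_dataset(rng, 10, groups)
        fits = sx.fit_gene_models(ds, sx.build_design(ds.groups, "cellmeans"))
        for j, g in enumerate(sx.GROUPS):
            mask = ds.groups == g
            means = ds.values.loc[:, mask.to_numpy()].mean(axis=1).to_numpy()
            assert np.allclose(fits.coefficients[:, j], means, atol=1e-12)

    def test_saturated_toy_model(self):
        cols = ["TCGA-0000011A"] + [f"TCGA-0000{i}01A" for i in range(1, 5)]
        frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["g0"], columns=cols)
        ds = sx.ExpressionDataset(
            frame, pd.Series(["control", "I", "II", "III", "IV"], index=cols, dtype=object)
        )
        fits = sx.fit_gene_models(ds, sx.build_design(ds.groups, "cellmeans"))
        assert fits.coefficients[0].tolist() == [1.0, 2.0, 3.0, 4.0, 5.0]
        assert fits.df_residual[0] == 0
        assert fits.sigma2[0] == 0

    def test_constant_gene_perfect_fit(self):
        groups = ["control"] * 3 + ["I"] * 3 + ["II"] * 3 + ["III"] * 3 + ["IV"] * 3
        ds = random_dataset(np.random.default_rng(0), 1, groups)
        ds.values.iloc[0] = 7.0
        fits = sx.fit_gene_models(ds, sx.build_design(ds.groups, "baseline"))
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(fits.coefficients[0, 1:], 0.0, atol=1e-12)

    def test_rank_deficient_design_names_columns(self):
        groups = ["control"] * 3 + ["I"] * 3
        ds = random_dataset(np.random.default_rng(1), 3, groups)
        X = sx.build_design(ds.groups, "baseline").matrix[:, :2]
        dup = DesignMatrix(np.hstack([X, X[:, 1:2]]), ("intercept", "I", "I_copy"), "baseline")
        with pytest.raises(LinModError, match="I_copy"):
            sx.fit_gene_models(ds, dup)

    def test_weighted_fit_matches_scaled_replication_oracle(self):
        """Integer weights equal ordinary least squares on replicated rows."""
        rng = np.random.default_rng(4)
        groups = ["control"] * 3 + ["I"] * 3 + ["II"] * 2 + ["III"] * 2 + ["IV"] * 2
        ds = random_dataset(rng, 5, groups)
        design = sx.build_design(ds.groups, "cellmeans")
        w = rng.integers(1, 4, size=ds.values.shape).astype(float)
        fits = sx.fit_gene_models(ds, design, weights=w)
        for g in range(5):
            rows = np.repeat(np.arange(len(groups)), w[g].astype(int))
            Xr = design.matrix[rows]
            yr = ds.values.iloc[g].to_numpy()[rows]
            beta = np.linalg.lstsq(Xr, yr, rcond=None)[0]
            assert np.allclose(fits.coefficients[g], beta, atol=1e-10)

    def test_non_positive_weights_rejected(self):
        groups = ["control", "I", "II", "III", "IV"] * 2
        ds = random_dataset(np.random.default_rng(5), 3, groups)
        design = sx.build_design(ds.groups, "cellmeans")
        w = np.ones(ds.values.shape)
        w[0, 0] = 0.0
        with pytest.raises(LinModError, match="strictly positive"):
            sx.fit_gene_models(ds, design, weights=w)


class TestMeanVarWeights:
    def test_flat_trend_gives_near_constant_weights(self):
        """With homoskedastic genes the fitted trend is flat, so every
        observation's weight is within 20% of the average weight."""
        cfg = sx.SimConfig(
            n_genes=1500,
            group_sizes=(10, 10, 10, 10, 10),
            prior_df=1e7,  # variance prior concentrates: all genes share one variance
            prior_var=0.25,
            class_fractions={"null": 1.0},
            seed=8,
        )
        ds, _ = sx.generate_dataset(cfg)
        design = sx.build_design(ds.groups, "baseline")
        w = sx.estimate_meanvar_weights(ds, design)
        ratio = w / w.mean()
        assert ratio.min() > 0.8 and ratio.max() < 1.2

    def test_weights_strictly_positive(self, balanced_cohort):
        _, ds, _ = balanced_cohort
        w = sx.estimate_meanvar_weights(ds, sx.build_design(ds.groups, "baseline"))
        assert np.all(w > 0)

    def test_too_few_genes_falls_back_to_unit_weights(self):
        groups = ["control"] * 3 + ["I"] * 3
        ds = random_dataset(np.random.default_rng(6), 5, groups)
        with pytest.warns(UserWarning, match="unit weights"):
            w = sx.estimate_meanvar_weights(ds, sx.build_design(ds.groups, "baseline"))
        assert np.all(w == 1.0)


@pytest.fixture(scope="module")
def fits():
    rng = np.random.default_rng(9)
    groups = ["control"] * 6 + ["I"] * 6 + ["II"] * 6 + ["III"] * 6 + ["IV"] * 6
    ds = random_dataset(rng, 60, groups)
    return sx.fit_gene_models(ds, sx.build_design(ds.groups, "baseline"))


class TestEbayes:
    def test_zero_prior_df_recovers_ordinary_t(self, fits):
        mod = sx.ebayes_moderate(fits, prior=(0.0, 1.0))
        se = fits.stdev_unscaled * np.sqrt(fits.sigma2)[:, None]
        assert np.allclose(mod.t, fits.coefficients / se, atol=1e-10)
        assert np.all(mod.df_total == fits.df_residual)

    def test_infinite_prior_df_pins_posterior_at_prior(self, fits):
        mod = sx.ebayes_moderate(fits, prior=(np.inf, 0.7))
        assert np.allclose(mod.var_post, 0.7)

    def test_posterior_variance_between_prior_and_sample(self, fits):
        mod = sx.ebayes_moderate(fits)
        lo = np.minimum(fits.sigma2, mod.var_prior)
        hi = np.maximum(fits.sigma2, mod.var_prior)
        assert np.all(mod.var_post >= lo - 1e-12) and np.all(mod.var_post <= hi + 1e-12)

    def test_zero_prior_df_moderated_f_equals_anova_f(self, fits):
        """With no shrinkage the joint stage F is the classical one-way
        ANOVA F, which scipy computes independently."""
        mod = sx.ebayes_moderate(fits, prior=(0.0, 1.0))
        # regenerate the same dataset the fixture fitted
        rng = np.random.default_rng(9)
        groups = ["control"] * 6 + ["I"] * 6 + ["II"] * 6 + ["III"] * 6 + ["IV"] * 6
        ds = random_dataset(rng, 60, groups)
        labels = np.array(groups)
        for g in range(10):
            y = ds.values.iloc[g].to_numpy()
            f_ref, p_ref = stats.f_oneway(*[y[labels == lab] for lab in sx.GROUPS])
            assert mod.f[g] == pytest.approx(f_ref, rel=1e-9)
            assert mod.p_f[g] == pytest.approx(p_ref, rel=1e-9)

    def test_moderated_t_p_matches_t_distribution(self, fits):
        mod = sx.ebayes_moderate(fits)
        p_ref = 2 * stats.t.sf(np.abs(mod.t), mod.df_total[:, None])
        assert np.allclose(mod.p_t, p_ref)
        assert np.all(mod.adj_p_t >= mod.p_t - 1e-15)

    def test_all_zero_residual_df_rejected(self):
        cols = ["TCGA-0000011A"] + [f"TCGA-0000{i}01A" for i in range(1, 5)]
        frame = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 5)), columns=cols,
            index=[f"g{i}" for i in range(4)],
        )
        ds = sx.ExpressionDataset(
            frame, pd.Series(["control", "I", "II", "III", "IV"], index=cols, dtype=object)
        )
        fits = sx.fit_gene_models(ds, sx.build_design(ds.groups, "cellmeans"))
        with pytest.raises(LinModError, match="no variance information"):
            sx.ebayes_moderate(fits)


def test_variance_prior_recovery_within_20_percent():
    """Method-of-moments hyperparameters recover the generating prior
    (d0=4, s0^2=0.05) from 10,000 simulated genes."""
    cfg = sx.SimConfig(
        n_genes=10_000,
        group_sizes=(4, 4, 4, 4, 4),
        prior_df=4.0,
        prior_var=0.05,
        class_fractions={"null": 1.0},
        seed=21,
    )
    ds, _ = sx.generate_dataset(cfg)
    fits = sx.fit_gene_models(ds, sx.build_design(ds.groups, "cellmeans"))
    d0, s0 = sx.fit_variance_prior(fits.sigma2, fits.df_residual)
    assert d0 == pytest.approx(4.0, rel=0.2)
    assert s0 == pytest.approx(0.05, rel=0.2)


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.1, 0.9), (0.015, 0.15, 0.9)),
            ((0.3,), (0.3,)),
        ],
    )
    def test_frozen_examples(self, p, expected):
        assert np.allclose(sx.adjust_bh(p), expected, atol=1e-12)

    def test_all_permutations_up_to_six_match_oracle(self):
        base = [0.001, 0.02, 0.2, 0.21, 0.6, 0.94]
        for n in range(1, 7):
            for perm in permutations(base[:n]):
                assert np.allclose(sx.adjust_bh(perm), bh_step_up_oracle(perm), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_property_matches_oracle(self, p):
        assert np.allclose(sx.adjust_bh(p), bh_step_up_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(LinModError):
            sx.adjust_bh(bad)


class TestRegulationStatus:
    @pytest.mark.parametrize(
        "lfcs,expected",
        [
            ((1.2, 2.0, 1.1, 0.5), "UP"),
            ((-1, -2, -1, -3), "DOWN"),
            ((1, -1, 1, 1), "MIXED"),
            ((0, 1, 1, 1), "MIXED"),  # zero is neither up nor down
        ],
    )
    def test_calls(self, lfcs, expected):
        assert sx.regulation_status(lfcs) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(LinModError):
            sx.regulation_status([1.0, 2.0])


def test_moderated_variance_weighted_combination():
    s2 = np.array([0.5, 2.0])
    d = np.array([10.0, 10.0])
    out = moderated_variance(s2, d, 5.0, 1.0)
    assert np.allclose(out, (5.0 * 1.0 + 10.0 * s2) / 15.0)
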
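"""ANOVA, MINQUE(1), BLUP and heritability."""

import numpy as np
import pandas as pd
import pytest

from sssl_epistasis.mixed_model import (
    Layout,
    VarianceComponents,
    anova_ems_components,
    estimate_vc_minque,
    fit_anova,
    fit_mixed_model,
    heritability,
    predict_blup,
    predict_ls,
)
from sssl_epistasis.truth import (
    TruthModel,
    generate_experiment,
    generate_vc_experiment,
    random_truth,
)


@pytest.fixture(scope="module")
def noisy_trial():
    return generate_vc_experiment(25, 4, 1, 4, n_materials=25, seed=3)


def anova_oracle(df):
    """Direct cell-means sums of squares for the balanced layout."""
    grand = df["hd"].mean()
    envs = sorted(df["env"].unique())
    mats = sorted(df["material"].unique())
    b = df.groupby("env")["block"].nunique().iloc[0]
    m, n_e = len(mats), len(envs)
    env_mean = df.groupby("env")["hd"].mean()
    mat_mean = df.groupby("material")["hd"].mean()
    cell = df.groupby(["env", "material"])["hd"].mean()
    blk = df.groupby(["env", "block"])["hd"].mean()
    ss_E = b * m * ((env_mean - grand) ** 2).sum()
    ss_B = m * sum(
        (blk[e] - env_mean[e]).pow(2).sum() for e in envs
    )
    ss_G = n_e * b * ((mat_mean - grand) ** 2).sum()
    ss_GE = b * sum(
        (cell[e] - env_mean[e] - mat_mean + grand).pow(2).sum() for e in envs
    )
    ss_tot = ((df["hd"] - grand) ** 2).sum()
    ss_err = ss_tot - ss_E - ss_B - ss_G - ss_GE
    return {
        "environments": ss_E,
        "blocks_within_env": ss_B,
        "genotypes": ss_G,
        "GxE": ss_GE,
        "error": ss_err,
        "total": ss_tot,
    }


class TestAnova:
    def test_mean_squares_match_cell_means_oracle(self, noisy_trial):
        an = fit_anova(noisy_trial)
        oracle = anova_oracle(noisy_trial)
        for src in ("environments", "blocks_within_env", "genotypes", "GxE", "error"):
            assert an.table.loc[src, "sum_sq"] == pytest.approx(
                oracle[src], rel=1e-8
            )

    def test_total_ss_identity_and_dfs(self, noisy_trial):
        an = fit_anova(noisy_trial)
        oracle = anova_oracle(noisy_trial)
        assert an.table["sum_sq"].sum() == pytest.approx(
            oracle["total"], rel=1e-8
        )
        n = len(noisy_trial)
        assert an.table["df"].sum() == n - 1
        lay = an.layout
        assert an.table.loc["GxE", "df"] == (lay.n_env - 1) * (lay.n_materials - 1)

    def test_noise_free_error_ms_is_zero(self, materials65):
        t = random_truth(materials65, seed=2, ge_scale=0.0)
        an = fit_anova(generate_experiment(t, materials65))
        assert an.error_ms == pytest.approx(0.0, abs=1e-18)
        assert an.table.loc["genotypes", "mean_sq"] > 1.0

    def test_interaction_detected(self, noisy_trial):
        an = fit_anova(noisy_trial)
        assert an.table.loc["GxE", "p"] < 0.01

    def test_rejects_degenerate_layouts(self):
        df = pd.DataFrame(
            {
                "env": ["e1"] * 4,
                "block": ["b1", "b1", "b2", "b2"],
                "material": ["A", "B", "A", "B"],
                "hd": [90.0, 91, 92, 93],
            }
        )
        with pytest.raises(ValueError, match="environments"):
            fit_anova(df)


class TestMinque:
    def test_equals_ems_on_balanced_design(self, noisy_trial):
        vc_m = estimate_vc_minque(noisy_trial)
        vc_e = anova_ems_components(fit_anova(noisy_trial))
        for k in vc_m.raw:
            assert vc_m.raw[k] == pytest.approx(
                vc_e.raw[k], rel=1e-8, abs=1e-8
            )

    def test_null_genotypic_variance_recovered(self):
        df = generate_vc_experiment(0.0, 0.0, 1.0, 4.0, n_materials=20, seed=5)
        vc = estimate_vc_minque(df)
        assert vc.sigma2_G < 1.0  # raw estimate fluctuates around zero
        assert vc.sigma2_e == pytest.approx(4.0, rel=0.35)

    def test_monte_carlo_unbiasedness(self):
        truth = np.array([25.0, 4.0, 1.0, 4.0])
        ests = []
        for i in range(50):
            df = generate_vc_experiment(
                *truth, n_materials=20, blocks_per_env=3, seed=700 + i
            )
            ests.append(list(estimate_vc_minque(df).raw.values()))
        ests = np.asarray(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - truth) <= 3.5 * se)

    def test_invalid_priors_rejected(self, noisy_trial):
        with pytest.raises(ValueError, match="priors"):
            estimate_vc_minque(noisy_trial, priors={"G": 0.0})

    def test_negative_estimates_truncated_with_warning(self):
        df = generate_vc_experiment(0.0, 0.0, 0.0, 1.0, n_materials=8, seed=11)
        with pytest.warns(UserWarning, match="truncated"):
            vc = estimate_vc_minque(df)
        assert min(vc.as_dict().values()) >= 0.0


class TestBlup:
    def test_zero_genotypic_variance_gives_zero_predictions(self, noisy_trial):
        vc = VarianceComponents(0.0, 2.0, 1.0, 4.0)
        preds = predict_blup(noisy_trial, vc)
        assert np.allclose(preds.G.to_numpy(), 0.0)

    def test_predictions_shrink_toward_zero(self, noisy_trial):
        vc = estimate_vc_minque(noisy_trial)
        blup = predict_blup(noisy_trial, vc)
        ls = predict_ls(noisy_trial)
        assert (blup.G.abs() <= ls.G.abs() + 1e-9).all()
        # genuinely shrunken, not merely equal
        assert blup.G.abs().sum() < ls.G.abs().sum()

    def test_ols_limit_recovers_centered_means(self, noisy_trial):
        # vanishing error variance: BLUP converges to the LS deviations
        vc = VarianceComponents(25.0, 4.0, 1.0, 1e-9)
        blup = predict_blup(noisy_trial, vc)
        ls = predict_ls(noisy_trial)
        assert np.allclose(blup.G.to_numpy(), ls.G.to_numpy(), atol=1e-6)

    def test_centering_invariants(self, noisy_trial):
        vc = estimate_vc_minque(noisy_trial)
        preds = predict_blup(noisy_trial, vc)
        assert abs(preds.G.sum()) < 1e-6
        assert preds.GE.sum(axis=0).abs().max() < 1e-6

    def test_invariance_to_constant_shift(self, noisy_trial):
        vc = estimate_vc_minque(noisy_trial)
        shifted = noisy_trial.assign(hd=noisy_trial["hd"] + 100.0)
        a = predict_blup(noisy_trial, vc)
        b = predict_blup(shifted, vc)
        assert np.allclose(a.G.to_numpy(), b.G.to_numpy(), atol=1e-8)
        assert np.allclose(a.GE.to_numpy(), b.GE.to_numpy(), atol=1e-8)

    def test_all_zero_variances_warns_and_zeroes(self, noisy_trial):
        vc = VarianceComponents(0.0, 0.0, 0.0, 1.0)
        with pytest.warns(UserWarning, match="zero"):
            preds = predict_blup(noisy_trial, vc)
        assert np.allclose(preds.G.to_numpy(), 0.0)
        assert np.allclose(preds.GE.to_numpy(), 0.0)


class TestHeritability:
    def test_proportions_by_construction(self):
        vc = VarianceComponents(31.78, 1.27, 0.0, 66.95)
        h2 = heritability(vc)
        assert h2.general == pytest.approx(0.3178, abs=1e-4)
        assert h2.peculiar == pytest.approx(0.0127, abs=1e-4)

    def test_zero_interaction_gives_zero_peculiar(self):
        vc = VarianceComponents(10.0, 0.0, 1.0, 4.0)
        assert heritability(vc).peculiar == 0.0

    def test_zero_phenotypic_variance_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(VarianceComponents(0.0, 0.0, 0.0, 0.0))

    def test_simulated_shares_recovered(self):
        truth = (20.0, 5.0, 2.0, 8.0)
        shares = []
        for i in range(30):
            df = generate_vc_experiment(*truth, n_materials=20, seed=400 + i)
            vc = estimate_vc_minque(df)
            if vc.total > 0:
                shares.append(heritability(vc).general)
        true_share = truth[0] / sum(truth)
        mean = np.mean(shares)
        se = np.std(shares, ddof=1) / np.sqrt(len(shares))
        assert abs(mean - true_share) <= max(3.5 * se, 0.03)

    def test_mean_basis_requires_layout(self):
        vc = VarianceComponents(10.0, 2.0, 1.0, 4.0)
        with pytest.raises(ValueError, match="layout"):
            heritability(vc, basis="mean")
        lay = Layout(
            environments=["e1", "e2", "e3"],
            blocks={e: ["b1", "b2", "b3"] for e in ("e1", "e2", "e3")},
            materials=["A", "B"],
        )
        h2 = heritability(vc, layout=lay, basis="mean")
        assert h2.general > heritability(vc).general


def test_fit_mixed_model_bundles_consistent_pieces():
    df = generate_vc_experiment(25, 4, 1, 4, n_materials=15, seed=21)
    res = fit_mixed_model(df)
    assert res.err.sigma2 == pytest.approx(res.anova.error_ms)
    assert set(res.blup.G.index) == set(res.ls.G.index)
    assert 0.0 <= res.heritability.general <= 1.0
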
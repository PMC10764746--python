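"""Effect decomposition: reference identities, round trips, significance."""

import numpy as np
import pytest

from sssl_epistasis.decompose import (
    EffectKind,
    decompose_effects,
    dominance_degree,
    estimate_dual_epistasis,
    estimate_effects_lm,
    estimate_mixed_epistasis,
    estimate_triple_epistasis,
)
from sssl_epistasis.mixed_model import fit_anova, fit_mixed_model, predict_ls
from sssl_epistasis.reference import load_reference_effects
from sssl_epistasis.truth import (
    generate_experiment,
    random_truth,
    truth_effect_table,
)


@pytest.fixture(scope="module")
def computed_duals():
    table = load_reference_effects(["additive", "dominance", "pyramiding"])
    return estimate_dual_epistasis(table)


@pytest.fixture(scope="module")
def computed_triples():
    table = load_reference_effects(
        ["additive", "dominance", "pyramiding", "dual_epistasis"]
    )
    estimate_mixed_epistasis(table)
    estimate_triple_epistasis(table)
    return table


class TestReferenceIdentities:
    """The residual operations reproduce the published effect values
    wherever every constituent of the residual was itself published."""

    @pytest.mark.parametrize(
        "material,expected",
        [
            ("Ehd1-1/Hd3a-1", -15.2),
            ("OsMADS50-1/Hd3a-1", -13.5),
            ("Hd3a-1/Hd1-1", -15.3),
            ("Ehd1-1/Hd3a-2", 13.0),
            ("Hd3a-2/Hd1-1", 9.1),
            ("OsMADS50-2/Hd3a-1", -18.6),
            ("OsMADS50-1/Hd3a-2", 7.2),
            ("OsMADS50-2/Hd1-1", -4.6),
        ],
    )
    def test_dual_epistasis_reproduces_printed_values(
        self, computed_duals, material, expected
    ):
        e = computed_duals.get(EffectKind.DUAL_EPI, material)
        assert e.available
        assert e.value == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "material,expected",
        [
            ("Ehd1-1/Hd3a-2/Hd1-1", 9.9),
            ("OsMADS50-1/Hd3a-1/Hd1-1", -16.0),
        ],
    )
    def test_mixed_epistasis_reproduces_printed_values(
        self, computed_triples, material, expected
    ):
        e = computed_triples.get(EffectKind.MIXED_EPI, material)
        assert e.value == pytest.approx(expected, abs=0.05)

    def test_triple_epistasis_from_mixed_minus_duals(self, computed_triples):
        e = computed_triples.get(EffectKind.TRIPLE_EPI, "Ehd1-1/Hd3a-2/Hd1-1")
        assert e.value == pytest.approx(-8.8, abs=0.05)

    def test_missing_constituent_flags_combination(self, computed_duals):
        # the Hd1 additive effect is unreported, so duals that need it are
        # undefined rather than zero
        e = computed_duals.get(EffectKind.DUAL_EPI, "Ehd1-1/Hd1-2")
        assert not e.available
        assert np.isnan(e.value)


class TestRoundTrip:
    """Noise-free simulation -> fit -> decompose recovers the exact truth."""

    @pytest.mark.parametrize("seed", [11, 37])
    def test_every_truth_effect_recovered(self, materials65, seed):
        t = random_truth(materials65, seed=seed)
        df = generate_experiment(t, materials65)
        fit = fit_mixed_model(df)
        table = decompose_effects(fit.ls, materials65, err=fit.err)
        truth = truth_effect_table(t, materials65)
        for e in truth.entries:
            got = table.get(e.kind, e.material)
            assert got.value == pytest.approx(e.value, abs=1e-9)
            for env, comp in e.env.items():
                assert got.env[env].value == pytest.approx(comp.value, abs=1e-9)

    def test_reconstruction_identities(self, materials65):
        # g = singles + duals + e3 and mixed = duals + e3, by construction
        t = random_truth(materials65, seed=5)
        df = generate_experiment(t, materials65)
        table = decompose_effects(predict_ls(df), materials65)
        for m in materials65:
            if m.order != 3:
                continue
            g = table.get(EffectKind.PYRAMIDING, m.material_id).value
            mixed = table.get(EffectKind.MIXED_EPI, m.material_id).value
            e3 = table.get(EffectKind.TRIPLE_EPI, m.material_id).value
            singles = sum(
                table.single_effect(l, s).value for l, s in m.states
            )
            duals = sum(
                table.get(EffectKind.DUAL_EPI, sub.material_id).value
                for sub in m.subsets(2)
            )
            assert g == pytest.approx(singles + duals + e3, abs=1e-9)
            assert mixed == pytest.approx(duals + e3, abs=1e-9)

    def test_env_interactions_sum_to_zero(self, materials65):
        t = random_truth(materials65, seed=8)
        df = generate_experiment(t, materials65)
        table = decompose_effects(predict_ls(df), materials65)
        for e in table.entries:
            if e.available and e.env:
                total = sum(c.value for c in e.env.values())
                assert abs(total) < 1e-6


class TestLmEstimator:
    def test_matches_sequential_on_saturated_design(self, materials65):
        t = random_truth(materials65, seed=13)
        df = generate_experiment(t, materials65)
        preds = predict_ls(df)
        seq = decompose_effects(preds, materials65)
        lm = estimate_effects_lm(preds, materials65)
        for e in seq.entries:
            if not e.available:
                continue
            got = lm.get(e.kind, e.material)
            assert got.value == pytest.approx(e.value, abs=1e-9)
            for env, comp in e.env.items():
                assert got.env[env].value == pytest.approx(comp.value, abs=1e-9)

    def test_invariant_to_material_row_order(self, materials65):
        t = random_truth(materials65, seed=14)
        df = generate_experiment(t, materials65)
        preds = predict_ls(df)
        a = estimate_effects_lm(preds, materials65)
        rng = np.random.default_rng(0)
        shuffled = list(materials65)
        rng.shuffle(shuffled)
        b = estimate_effects_lm(preds, shuffled)
        for e in a.entries:
            assert b.get(e.kind, e.material).value == pytest.approx(
                e.value, abs=1e-9
            )

    def test_singles_only_design_has_no_epistasis_columns(self, loci, materials65):
        singles = [m for m in materials65 if m.order <= 1]
        t = random_truth(materials65, seed=15)
        df = generate_experiment(t, singles)
        preds = predict_ls(df)
        lm = estimate_effects_lm(preds, singles)
        assert not lm.level(EffectKind.DUAL_EPI)
        seq = decompose_effects(preds, singles)
        for kind in (EffectKind.ADDITIVE, EffectKind.DOMINANCE):
            for e in seq.level(kind):
                assert lm.get(kind, e.material).value == pytest.approx(
                    e.value, abs=1e-9
                )


class TestSignificance:
    def test_zero_effect_with_positive_se_is_not_significant(self, materials33):
        from sssl_epistasis.truth import TruthModel

        t = TruthModel(block_sd=0.5, resid_sd=1.0, seed=2)
        df = generate_experiment(t, materials33)
        an = fit_anova(df)
        table = decompose_effects(predict_ls(df), materials33, err=an.error_context())
        # under an all-null truth the vast majority of effects must be null
        ps = [e.p for e in table.entries if e.p is not None]
        assert ps and np.mean(np.array(ps) <= 0.05) < 0.25

    def test_large_effect_is_detected(self, materials33):
        from sssl_epistasis.truth import TruthModel

        t = TruthModel(
            a={"Hd3a-2": 5.0}, block_sd=0.5, resid_sd=1.0, seed=3
        )
        df = generate_experiment(t, materials33)
        an = fit_anova(df)
        table = decompose_effects(predict_ls(df), materials33, err=an.error_context())
        e = table.get(EffectKind.ADDITIVE, "Hd3a-2")
        assert e.stars == "**"

    def test_zero_residual_df_withholds_stars(self, materials33):
        from sssl_epistasis.decompose import ErrorContext
        from sssl_epistasis.truth import TruthModel

        t = TruthModel(a={"Hd3a-2": 5.0}, seed=4)
        df = generate_experiment(t, materials33)
        err = ErrorContext(sigma2=1.0, df=0, n_env=3, n_blocks=3)
        table = decompose_effects(predict_ls(df), materials33, err=err)
        e = table.get(EffectKind.ADDITIVE, "Hd3a-2")
        assert e.p is None and e.stars == ""


class TestDominanceDegree:
    @pytest.mark.parametrize(
        "a,d,ratio,label",
        [
            (4.0, 8.0, 2.0, "super-dominant"),
            (2.0, 1.0, 0.5, "partial dominance"),
            (2.1, 2.7, 2.7 / 2.1, "super-dominant"),
        ],
    )
    def test_ratio_and_label(self, a, d, ratio, label):
        res = dominance_degree(a, d)
        assert res.ratio == pytest.approx(ratio)
        assert res.label == label

    def test_zero_additive_is_dominance_only(self):
        res = dominance_degree(0.0, 3.0)
        assert res.ratio is None
        assert res.label == "dominance only"
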
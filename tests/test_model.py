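"""Energy-model container, loss, splits, resampling and evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foldspace.constants import RT, TRAIT_FOLDING, TRAIT_BINDING
from foldspace.genotypes import GenotypeTable
from foldspace.model import (
    EnergyModel,
    FitConfig,
    LinearInteractionRegressor,
    classify_and_test,
    pair_index,
    pairwise_design,
    resample_training,
    split_variants,
    variance_explained,
    weighted_mae_loss,
)


@pytest.fixture
def k3_model():
    """K=3 order-2 model with hand-picked coefficients."""
    return EnergyModel(
        traits=(TRAIT_FOLDING,),
        dg_wt={TRAIT_FOLDING: -2.0},
        ddg={TRAIT_FOLDING: np.array([1.0, -0.5, 2.0])},
        couplings={TRAIT_FOLDING: np.array([0.3, -0.1, 0.7])},  # (01, 02, 12)
        affine={"abundance": (0.1, 0.8)},
    )


class TestVariantFreeEnergy:
    def test_wildtype_is_dg_wt(self, k3_model):
        assert k3_model.free_energy([0, 0, 0], TRAIT_FOLDING)[0] == pytest.approx(-2.0)

    def test_single_adds_one_term(self, k3_model):
        assert k3_model.free_energy([0, 1, 0], TRAIT_FOLDING)[0] == pytest.approx(-2.5)

    def test_pair_adds_coupling(self, k3_model):
        # genotype 110: dg_wt + ddg_0 + ddg_1 + coupling_01
        expected = -2.0 + 1.0 - 0.5 + 0.3
        assert k3_model.free_energy([1, 1, 0], TRAIT_FOLDING)[0] == pytest.approx(expected)

    def test_brute_force_sum_over_all_genotypes(self, k3_model):
        """Explicit enumeration oracle over all 8 genotypes."""
        pairs = pair_index(3)
        for g in range(8):
            x = [(g >> i) & 1 for i in range(3)]
            expected = -2.0 + sum(
                xi * d for xi, d in zip(x, k3_model.ddg[TRAIT_FOLDING]))
            expected += sum(k3_model.couplings[TRAIT_FOLDING][p] * x[i] * x[j]
                            for p, (i, j) in enumerate(pairs))
            assert k3_model.free_energy(x, TRAIT_FOLDING)[0] == pytest.approx(expected)

    def test_dimension_mismatch(self, k3_model):
        with pytest.raises(ValueError):
            k3_model.free_energy([1, 0], TRAIT_FOLDING)


class TestPredictFitness:
    def test_identity_transform_returns_probability(self, k3_model):
        m = EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: 0.0},
                        ddg={TRAIT_FOLDING: np.zeros(3)},
                        couplings={TRAIT_FOLDING: None},
                        affine={"abundance": (0.0, 1.0)})
        assert m.predict_fitness([0, 0, 0], "abundance")[0] == pytest.approx(0.5)

    def test_lower_plateau_is_intercept(self, k3_model):
        m = EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: 50.0},
                        ddg={TRAIT_FOLDING: np.zeros(3)},
                        couplings={TRAIT_FOLDING: None},
                        affine={"abundance": (-0.1, 1.0)})
        assert m.predict_fitness([0, 0, 0], "abundance")[0] == pytest.approx(-0.1)

    def test_hand_computed_value(self, k3_model):
        from foldspace.states import fraction_folded
        x = [1, 0, 1]
        dg = -2.0 + 1.0 + 2.0 - 0.1
        expected = 0.1 + 0.8 * fraction_folded(dg)
        assert k3_model.predict_fitness(x, "abundance")[0] == pytest.approx(expected)

    def test_unknown_phenotype(self, k3_model):
        with pytest.raises(ValueError):
            k3_model.predict_fitness([0, 0, 0], "binding")

    def test_zero_affine_scale_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: 0.0},
                        ddg={TRAIT_FOLDING: np.zeros(2)},
                        couplings={TRAIT_FOLDING: None},
                        affine={"abundance": (0.0, 0.0)})


class TestWeightedMaeLoss:
    def test_perfect_fit_is_zero(self):
        assert weighted_mae_loss([1.0, 2.0], [1.0, 2.0], [0.1, 0.1]) == 0.0

    def test_forced_arithmetic(self):
        assert weighted_mae_loss([0.5], [1.0], [0.5]) == pytest.approx(1.0)

    def test_l2_term_adds_regularization(self):
        theta = np.zeros(10)
        theta[0] = 1000.0
        base = weighted_mae_loss([0.5], [1.0], [0.5])
        reg = weighted_mae_loss([0.5], [1.0], [0.5], theta=theta, l2=1e-6)
        assert reg - base == pytest.approx(1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            weighted_mae_loss([1.0], [1.0], [0.0])

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, ys):
        ys = np.asarray(ys)
        preds = ys * 0.5 + 0.1
        sig = np.full_like(ys, 0.3)
        perm = np.random.default_rng(0).permutation(len(ys))
        assert weighted_mae_loss(preds, ys, sig) == pytest.approx(
            weighted_mae_loss(preds[perm], ys[perm], sig[perm]))


class TestSplitVariants:
    def test_sizes_and_determinism(self):
        labels = split_variants(1000, seed=5)
        sizes = pd.Series(labels).value_counts()
        assert abs(sizes["train"] - 700) <= 1
        assert abs(sizes["val"] - 200) <= 1
        assert abs(sizes["test"] - 100) <= 1
        np.testing.assert_array_equal(labels, split_variants(1000, seed=5))

    def test_different_seeds_differ(self):
        a = split_variants(1000, seed=1)
        b = split_variants(1000, seed=2)
        assert (a != b).any()

    def test_wildtype_forced_to_training(self):
        G = np.zeros((20, 4), dtype=int)
        for i in range(1, 20):
            G[i, :] = [(i >> j) & 1 for j in range(4)]
        table = GenotypeTable(genotypes=G[:16])
        for seed in range(20):
            labels = split_variants(table, seed=seed)
            assert labels[table.wildtype_index()] == "train"

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_variants(9)


class TestResampleTraining:
    def _table(self, n, sigma, seed=0):
        rng = np.random.default_rng(seed)
        cols = max(int(np.ceil(np.log2(n))), 1)
        G = (np.arange(n)[:, None] >> np.arange(cols)) & 1
        t = GenotypeTable(genotypes=G)
        t.fitness["abundance"] = rng.normal(0, 1, n)
        t.sigma["abundance"] = np.full(n, sigma)
        return t

    def test_standardized_perturbation_has_unit_sd(self):
        t = self._table(100_000, 0.3)
        out = resample_training(t, seed=1)
        z = (out.fitness["abundance"] - t.fitness["abundance"]) / 0.3
        assert z.std() == pytest.approx(1.0, rel=0.02)

    def test_tiny_sigma_leaves_fitness_unchanged(self):
        t = self._table(100, 1e-12)
        out = resample_training(t, seed=1)
        np.testing.assert_allclose(out.fitness["abundance"],
                                   t.fitness["abundance"], atol=1e-9)

    def test_seed_reproducibility_and_mask(self):
        t = self._table(100, 0.3)
        a = resample_training(t, seed=7)
        b = resample_training(t, seed=7)
        np.testing.assert_array_equal(a.fitness["abundance"], b.fitness["abundance"])
        mask = np.zeros(100, dtype=bool)  # nothing resampled
        c = resample_training(t, seed=7, mask=mask)
        np.testing.assert_array_equal(c.fitness["abundance"], t.fitness["abundance"])


class TestLinearBaseline:
    def test_parameter_counts(self):
        from math import comb
        for k, order in [(34, 1), (10, 2), (8, 3)]:
            X = np.zeros((2, k))
            est = LinearInteractionRegressor(max_order=order)
            d = est._design(X)
            assert d.shape[1] == 1 + sum(comb(k, o) for o in range(1, order + 1))

    def test_exact_recovery_of_additive_fitness(self):
        rng = np.random.default_rng(0)
        G = ((np.arange(64)[:, None] >> np.arange(6)) & 1).astype(float)
        beta = rng.normal(0, 1, 6)
        y = 0.5 + G @ beta
        est = LinearInteractionRegressor(max_order=1).fit(G, y)
        np.testing.assert_allclose(est.predict(G), y, atol=1e-10)

    def test_underdetermined_rejected(self):
        X = np.zeros((5, 10))
        with pytest.raises(ValueError, match="underdetermined"):
            LinearInteractionRegressor(max_order=2).fit(X, np.zeros(5))


class TestVarianceExplained:
    def _setup(self):
        m = EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: 0.0},
                        ddg={TRAIT_FOLDING: np.array([1.0, 2.0])},
                        couplings={TRAIT_FOLDING: None},
                        affine={"abundance": (0.0, 1.0)})
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        return m, X

    def test_perfect_predictions_give_one(self):
        m, X = self._setup()
        y = m.predict_fitness(X, "abundance")
        assert variance_explained(m, X, {"abundance": y})["abundance"] == pytest.approx(1.0)

    def test_mean_predictor_gives_zero(self):
        m, X = self._setup()
        y = m.predict_fitness(X, "abundance")
        # a flat model predicting exactly mean(y) everywhere
        const = EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: 0.0},
                            ddg={TRAIT_FOLDING: np.zeros(2)},
                            couplings={TRAIT_FOLDING: None},
                            affine={"abundance": (y.mean() - 0.5e-9, 1e-9)})
        r2 = variance_explained(const, X, {"abundance": y})["abundance"]
        assert r2 == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_residuals(self):
        m, X = self._setup()
        y = m.predict_fitness(X, "abundance") + np.array([0.1, -0.1, 0.1, -0.1])
        expected = 1.0 - 4 * 0.01 / np.sum((y - y.mean()) ** 2)
        assert variance_explained(m, X, {"abundance": y})["abundance"] == pytest.approx(expected)

    def test_degenerate_subsets_rejected(self):
        m, X = self._setup()
        with pytest.raises(ValueError):
            variance_explained(m, X[:0], {"abundance": np.array([])})
        with pytest.raises(ValueError):
            variance_explained(m, X, {"abundance": np.ones(4)})


class TestClassifyAndTest:
    def _table(self):
        G = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        t = GenotypeTable(genotypes=G)
        t.fitness["abundance"] = np.array([1.0, 1.0, 0.4, 0.2])
        t.sigma["abundance"] = np.array([0.05, 0.05, 0.05, 0.05])
        return t

    def _model(self, dg_wt=0.0):
        return EnergyModel(traits=(TRAIT_FOLDING,), dg_wt={TRAIT_FOLDING: dg_wt},
                           ddg={TRAIT_FOLDING: np.array([0.0, 3.0])},
                           couplings={TRAIT_FOLDING: None},
                           affine={"abundance": (0.0, 1.0)})

    def test_equal_fitness_is_indistinguishable(self):
        out = classify_and_test(self._table(), self._model(-1.0))
        assert out.loc[1, "p_abundance"] == pytest.approx(1.0)
        assert bool(out.loc[1, "wt_indistinguishable_abundance"])

    def test_z_boundary_value(self):
        t = self._table()
        # z = 1.96 at |y - y_wt| = 1.96 * sqrt(2) * 0.05
        t.fitness["abundance"][2] = 1.0 - 1.96 * np.sqrt(2) * 0.05
        out = classify_and_test(t, self._model(-1.0))
        assert out.loc[2, "p_abundance"] == pytest.approx(0.05, abs=1e-3)

    def test_tie_at_half_classifies_not_folded(self):
        out = classify_and_test(self._table(), self._model(dg_wt=0.0))
        # wild type sits exactly at p_f = 0.5 -> strict inequality
        assert not bool(out.loc[0, "folded"])

    def test_missing_sigma_rejected(self):
        t = self._table()
        del t.sigma["abundance"]
        with pytest.raises(ValueError):
            classify_and_test(t, self._model())


class TestSerialization:
    def test_model_round_trip(self, k3_model, tmp_path):
        path = tmp_path / "model.json"
        k3_model.save(path)
        back = EnergyModel.load(path)
        np.testing.assert_allclose(back.ddg[TRAIT_FOLDING],
                                   k3_model.ddg[TRAIT_FOLDING])
        np.testing.assert_allclose(back.couplings[TRAIT_FOLDING],
                                   k3_model.couplings[TRAIT_FOLDING])
        assert back.affine == k3_model.affine
        assert back.dg_wt == k3_model.dg_wt

    def test_canonicalization_preserves_predictions(self, k3_model):
        flipped = EnergyModel(
            traits=k3_model.traits,
            dg_wt={TRAIT_FOLDING: -k3_model.dg_wt[TRAIT_FOLDING]},
            ddg={TRAIT_FOLDING: -k3_model.ddg[TRAIT_FOLDING]},
            couplings={TRAIT_FOLDING: -k3_model.couplings[TRAIT_FOLDING]},
            affine={"abundance": (0.1 + 0.8, -0.8)},
        )
        canon = flipped.canonicalized()
        assert canon.affine["abundance"][1] > 0
        X = ((np.arange(8)[:, None] >> np.arange(3)) & 1).astype(float)
        np.testing.assert_allclose(canon.predict_fitness(X, "abundance"),
                                   flipped.predict_fitness(X, "abundance"))
        np.testing.assert_allclose(canon.predict_fitness(X, "abundance"),
                                   k3_model.predict_fitness(X, "abundance"))


class TestFitConfig:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            FitConfig(split_fractions=(0.5, 0.3, 0.1))

    def test_order_validated(self):
        with pytest.raises(ValueError):
            FitConfig(max_interaction_order=3)


def test_pairwise_design_matches_outer_products():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 2, size=(20, 5)).astype(float)
    P = pairwise_design(X)
    for col, (i, j) in enumerate(pair_index(5)):
        np.testing.assert_array_equal(P[:, col], X[:, i] * X[:, j])
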
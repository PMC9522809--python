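import numpy as np
import pytest

import scentmap.autoencoder as ae
from scentmap.autoencoder import AEConfig, cross_validate, encode, grid_search
from scentmap.spectra import window_and_normalize


def _toy_config(sizes=(6, 4, 2, 4, 6), **kw):
    defaults = dict(layer_sizes=sizes, epochs=5, seed=3, batch_size=4)
    defaults.update(kw)
    return AEConfig(**defaults)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestForward:
    def test_zero_weights_give_half_everywhere(self, rng):
        cfg = _toy_config()
        model = ae.init_model(cfg)
        model.weights = [np.zeros_like(w) for w in model.weights]
        model.biases = [np.zeros_like(b) for b in model.biases]
        x = rng.random((3, 6))
        latent, recon = ae.forward(model, x)
        np.testing.assert_array_equal(latent, 0.5)
        np.testing.assert_array_equal(recon, 0.5)

    def test_forward_is_pure(self, rng):
        model = ae.init_model(_toy_config())
        x = rng.random((4, 6))
        a = ae.forward(model, x)
        b = ae.forward(model, x)
        np.testing.assert_array_equal(a[1], b[1])

    def test_hand_computed_sigmoid_chain(self):
        """4-2-1-2-4 net with hand-set weights vs an explicit chain."""
        cfg = _toy_config(sizes=(4, 2, 1, 2, 4))
        model = ae.init_model(cfg)
        model.weights = [
            np.full((4, 2), 0.5),
            np.full((2, 1), -1.0),
            np.full((1, 2), 2.0),
            np.full((2, 4), 0.25),
        ]
        model.biases = [np.array([0.1, -0.1]), np.array([0.3]),
                        np.array([0.0, 0.2]), np.full(4, -0.5)]
        x = np.array([[0.2, 0.4, 0.6, 0.8]])
        a1 = _sigmoid(x @ model.weights[0] + model.biases[0])
        a2 = _sigmoid(a1 @ model.weights[1] + model.biases[1])
        a3 = _sigmoid(a2 @ model.weights[2] + model.biases[2])
        a4 = _sigmoid(a3 @ model.weights[3] + model.biases[3])
        latent, recon = ae.forward(model, x)
        np.testing.assert_allclose(latent, a2, atol=1e-14)
        np.testing.assert_allclose(recon, a4, atol=1e-14)

    def test_dimension_mismatch_raises(self, rng):
        model = ae.init_model(_toy_config())
        with pytest.raises(ValueError):
            ae.forward(model, rng.random((2, 5)))


class TestLoss:
    def test_zero_coefficients_reduce_to_mean_summed_mse(self, rng):
        cfg = _toy_config(l2_coeff=0.0, sparsity_coeff=0.0)
        model = ae.init_model(cfg)
        x = rng.random((5, 6))
        _, recon = ae.forward(model, x)
        parts = ae.loss(model, x)
        expected = np.sum((recon - x) ** 2) / 5
        assert parts.l2 == 0 and parts.sparsity == 0
        np.testing.assert_allclose(parts.total, expected, rtol=1e-12)

    def test_perfect_reconstruction_gives_zero(self, rng):
        cfg = _toy_config(l2_coeff=0.0, sparsity_coeff=0.0)
        model = ae.init_model(cfg)
        x = rng.random((5, 6))
        parts = ae.loss(model, x, reconstructions=x)
        assert parts.reconstruction == 0.0

    def test_sparsity_zero_when_target_equals_mean_activation(self):
        assert ae._kl_sparsity(0.05, np.array([0.05, 0.05])) == pytest.approx(0.0)

    def test_sparsity_matches_scalar_kl_oracle(self):
        rho, rho_hat = 0.05, np.array([0.1, 0.2])
        expected = sum(
            rho * np.log(rho / r) + (1 - rho) * np.log((1 - rho) / (1 - r))
            for r in rho_hat
        )
        np.testing.assert_allclose(ae._kl_sparsity(rho, rho_hat), expected, rtol=1e-12)

    def test_parts_nonnegative_and_total_is_sum(self, rng):
        model = ae.init_model(_toy_config(l2_coeff=0.01, sparsity_coeff=0.5))
        x = rng.random((8, 6))
        p = ae.loss(model, x)
        assert p.reconstruction >= 0 and p.l2 >= 0 and p.sparsity >= 0
        assert abs(p.total - (p.reconstruction + p.l2 + p.sparsity)) < 1e-10

    @pytest.mark.parametrize("attr,part", [("l2_coeff", "l2"),
                                           ("sparsity_coeff", "sparsity")])
    def test_monotone_penalty_in_coefficient(self, rng, attr, part):
        x = rng.random((6, 6))
        vals = []
        for coeff in (0.01, 0.1, 1.0):
            cfg = _toy_config(**{attr: coeff})
            model = ae.init_model(cfg)  # same seed -> same weights
            vals.append(getattr(ae.loss(model, x), part))
        assert vals[0] <= vals[1] <= vals[2]


class TestGradients:
    @pytest.mark.parametrize("l2,beta,layers", [
        (0.0, 0.0, "bottleneck"),
        (0.01, 0.0, "bottleneck"),
        (0.001, 0.7, "bottleneck"),
        (0.001, 0.7, "all_hidden"),
    ])
    def test_analytic_matches_central_differences(self, rng, l2, beta, layers):
        cfg = _toy_config(l2_coeff=l2, sparsity_coeff=beta, sparsity_layers=layers)
        model = ae.init_model(cfg)
        x = rng.random((5, 6))
        gw, gb, _ = ae.gradients(model, x)
        eps = 1e-6
        for l in range(len(model.weights)):
            r, c = model.weights[l].shape
            for idx in [(0, 0), (2 % r, 1 % c), (r - 1, c - 1)]:
                orig = model.weights[l][idx]
                model.weights[l][idx] = orig + eps
                up = ae.loss(model, x).total
                model.weights[l][idx] = orig - eps
                dn = ae.loss(model, x).total
                model.weights[l][idx] = orig
                num = (up - dn) / (2 * eps)
                assert abs(gw[l][idx] - num) <= 1e-5 * max(1.0, abs(num))
            orig = model.biases[l][0]
            model.biases[l][0] = orig + eps
            up = ae.loss(model, x).total
            model.biases[l][0] = orig - eps
            dn = ae.loss(model, x).total
            model.biases[l][0] = orig
            num = (up - dn) / (2 * eps)
            assert abs(gb[l][0] - num) <= 1e-5 * max(1.0, abs(num))


class TestTrain:
    def test_loss_descends_on_synthetic_spectra(self, tiny_dataset):
        mat = window_and_normalize(tiny_dataset.spectra)
        cfg = AEConfig(layer_sizes=(212, 20, 8, 20, 212), epochs=30, seed=1)
        model = ae.train(cfg, mat)
        assert model.training_history[-1] < model.training_history[0]

    def test_same_seed_gives_identical_history(self, rng):
        x = rng.random((12, 6))
        cfg = _toy_config(epochs=10)
        h1 = ae.train(cfg, x).training_history
        h2 = ae.train(cfg, x).training_history
        assert h1 == h2  # bitwise

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ae.train(_toy_config(), np.zeros((1, 6)))


class TestCrossValidate:
    def test_partition_disjoint_and_exhaustive(self, rng):
        x = rng.random((10, 6))
        res = cross_validate(_toy_config(epochs=2), x, folds=5)
        assert res.fold_sizes == [2, 2, 2, 2, 2]
        assert len(res.fold_errors) == 5

    def test_duplicated_samples_have_no_generalization_gap(self, rng):
        row = rng.random(6)
        x = np.tile(row, (10, 1))
        cfg = _toy_config(epochs=200, learning_rate=0.5,
                          l2_coeff=0.0, sparsity_coeff=0.0)
        res = cross_validate(cfg, x, folds=5)
        model = ae.train(cfg, x)
        train_err = ae.reconstruction_error(model, x)
        # both errors collapse to ~0 with no train/test gap
        assert res.mean_error == pytest.approx(train_err, abs=1e-4)

    def test_mean_matches_manual_fold_loop(self, rng):
        x = rng.random((10, 6))
        cfg = _toy_config(epochs=3)
        res = cross_validate(cfg, x, folds=2)
        # independent re-implementation of the split + evaluation
        order = np.random.default_rng(cfg.seed).permutation(10)
        parts = np.array_split(order, 2)
        manual = []
        for i in range(2):
            tr = np.concatenate([p for j, p in enumerate(parts) if j != i])
            model = ae.train(cfg, x[tr])
            manual.append(ae.reconstruction_error(model, x[parts[i]]))
        np.testing.assert_allclose(res.fold_errors, manual, rtol=1e-12)

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(_toy_config(), rng.random((3, 6)), folds=5)


class TestEncode:
    def test_shape_ids_and_consistency_with_forward(self, tiny_dataset):
        mat = window_and_normalize(tiny_dataset.spectra)
        cfg = AEConfig(layer_sizes=(212, 20, 8, 20, 212), epochs=5, seed=1)
        model = ae.train(cfg, mat)
        lat = encode(model, mat)
        assert lat.values.shape == (len(mat.molecule_ids), 8)
        assert lat.molecule_ids == mat.molecule_ids
        lat2 = encode(model, mat)
        np.testing.assert_array_equal(lat.values, lat2.values)
        direct, _ = ae.forward(model, mat.values)
        np.testing.assert_array_equal(lat.values, direct)


class TestGridSearch:
    def test_corrupted_learning_rate_ranks_last(self, rng):
        x = rng.random((12, 6))
        sane = _toy_config(epochs=20)
        crazy = _toy_config(epochs=20, learning_rate=80.0)
        ranked = grid_search([crazy, sane], x, folds=2)
        assert ranked[0][0].learning_rate == sane.learning_rate

    def test_single_config_returned_as_rank_one(self, rng):
        x = rng.random((8, 6))
        cfg = _toy_config(epochs=2)
        ranked = grid_search([cfg], x, folds=2)
        assert len(ranked) == 1 and ranked[0][0] is cfg

    def test_ranking_matches_direct_cv_scores(self, rng):
        x = rng.random((10, 6))
        configs = [_toy_config(epochs=2, seed=s) for s in (1, 2, 3)]
        ranked = grid_search(configs, x, folds=2)
        direct = {id(c): cross_validate(c, x, 2).mean_error for c in configs}
        scores = [direct[id(c)] for c, _ in ranked]
        assert scores == sorted(scores)


def test_latent_codes_cluster_by_archetype(tiny_dataset):
    """Same-archetype pairs sit closer in latent space than cross pairs."""
    mat = window_and_normalize(tiny_dataset.spectra)
    cfg = AEConfig(layer_sizes=(212, 24, 8, 24, 212), epochs=80, seed=2)
    lat = encode(ae.train(cfg, mat), mat)
    truth = tiny_dataset.truth
    same, cross = [], []
    for i, a in enumerate(lat.molecule_ids):
        for b in lat.molecule_ids[i + 1 :]:
            d = np.linalg.norm(lat.row(a) - lat.row(b))
            (same if truth[a] == truth[b] else cross).append(d)
    assert np.mean(same) < np.mean(cross)


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = _toy_config(epochs=4)
    model = ae.train(cfg, rng.random((8, 6)))
    path = tmp_path / "model.json"
    ae.save_model(model, path)
    back = ae.load_model(path)
    assert back.config == model.config
    for w1, w2 in zip(model.weights, back.weights):
        np.testing.assert_array_equal(w1, w2)
    assert back.training_history == model.training_history
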
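"""Fusion network mechanics and the training loop."""

import numpy as np
import pytest

from synergraph import (ModelConfig, SynergyModel, SyntheticSpec,
                        make_synthetic_study, mse_loss)
from synergraph.autodiff import Tensor
from synergraph.nn import MLP


@pytest.fixture(scope="module")
def small_study():
    return make_synthetic_study(
        SyntheticSpec(n_drugs=10, n_cell_lines=2, density=1.0, seed=11))


@pytest.fixture(scope="module")
def small_fit(small_study):
    ds, _ = small_study
    cfg = ModelConfig(d=8, latent=16, modality_hidden=32, pred_hidden=(32,),
                      mol_layers=(16, 16), epochs=4, batch_size=None, seed=1)
    return SynergyModel(ds, config=cfg).fit()


class TestMseLoss:
    def test_examples(self):
        assert mse_loss([(1.0, 1.0), (2.0, 2.0)]) == 0.0
        assert mse_loss([(0, 1), (2, 0)]) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            mse_loss([])

    def test_matches_loop_oracle(self, rng):
        pairs = rng.standard_normal((100, 2))
        expect = sum((y - yh) ** 2 for y, yh in pairs) / 100
        assert abs(mse_loss(pairs) - expect) < 1e-12


class TestFusionMechanics:
    def test_projected_width_is_block_sum(self, small_fit):
        net = small_fit.network
        lat = net.config.latent
        g = np.zeros((2, small_fit.ctx.expression.shape[1]))
        s = np.zeros((2, net.config.mol_layers[-1]))
        x = np.zeros((2, small_fit.ctx.X.shape[1]))
        h = np.zeros((2, net.h_dim))
        net.set_training(False)
        z = net.project_and_fuse(g, s, s, x, x, h, h)
        assert z.data.shape == (2, 7 * lat)

    def test_pair_swap_permutes_blocks(self, small_fit, rng):
        """Swapping (i, j) only permutes the paired (s, x, h) blocks."""
        net = small_fit.network
        lat = net.config.latent
        net.set_training(False)
        g = rng.standard_normal((1, small_fit.ctx.expression.shape[1]))
        s_i = rng.standard_normal((1, net.config.mol_layers[-1]))
        s_j = rng.standard_normal((1, net.config.mol_layers[-1]))
        x_i = rng.standard_normal((1, small_fit.ctx.X.shape[1]))
        x_j = rng.standard_normal((1, small_fit.ctx.X.shape[1]))
        h_i = rng.standard_normal((1, net.h_dim))
        h_j = rng.standard_normal((1, net.h_dim))
        z_ij = net.project_and_fuse(g, s_i, s_j, x_i, x_j, h_i, h_j).data
        z_ji = net.project_and_fuse(g, s_j, s_i, x_j, x_i, h_j, h_i).data
        blocks_ij = z_ij.reshape(7, lat)
        blocks_ji = z_ji.reshape(7, lat)
        perm = [0, 2, 1, 4, 3, 6, 5]
        np.testing.assert_allclose(blocks_ji, blocks_ij[perm], atol=1e-12)

    def test_eval_prediction_deterministic(self, small_fit):
        i = np.array([0, 0]); j = np.array([3, 3]); r = np.array([1, 1])
        out = small_fit.predict_triplets(i, j, r)
        assert out[0] == out[1]
        again = small_fit.predict_triplets(i, j, r)
        np.testing.assert_array_equal(out, again)

    def test_symmetric_evaluation_order_invariant(self, small_fit):
        a = small_fit.predict_triplets([1], [4], [0])
        b = small_fit.predict_triplets([4], [1], [0])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_tiny_mlp_pencil_and_paper(self):
        """Hand-set 2-3-1 network without normalization."""
        mlp = MLP([2, 3, 1], np.random.default_rng(0), batch_norm=False)
        lin1, _, lin2 = mlp.layers
        lin1.weight.data = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]])
        lin1.bias.data = np.array([0.0, 1.0, 0.0])
        lin2.weight.data = np.array([[1.0], [1.0], [2.0]])
        lin2.bias.data = np.array([-0.5])
        x = np.array([[2.0, 1.0]])
        hidden = np.maximum(x @ lin1.weight.data + lin1.bias.data, 0)  # [2, 1, .5]
        expect = hidden @ lin2.weight.data - 0.5                       # 3.5
        out = mlp(Tensor(x))
        np.testing.assert_allclose(out.data, expect)
        assert out.data[0, 0] == pytest.approx(3.5)


class TestTraining:
    def test_same_seed_identical_histories(self, small_study):
        ds, _ = small_study
        cfg = ModelConfig(d=8, latent=16, modality_hidden=32, pred_hidden=(32,),
                          mol_layers=(16, 16), epochs=3, batch_size=None, seed=5)
        h1 = SynergyModel(ds, config=cfg).fit().loss_history
        h2 = SynergyModel(ds, config=cfg).fit().loss_history
        np.testing.assert_array_equal(h1, h2)

    def test_loss_decreases_with_training(self, small_fit):
        assert small_fit.loss_history[-1] < small_fit.loss_history[0]

    def test_empty_training_fold_rejected(self, small_study):
        ds, _ = small_study
        model = SynergyModel(ds, config=ModelConfig(epochs=1))
        with pytest.raises(ValueError, match="empty training fold"):
            model.fit(train_idx=[])

    def test_unknown_switch_rejected(self, small_study):
        ds, _ = small_study
        with pytest.raises(ValueError, match="unknown component"):
            SynergyModel(ds, switches={"warp_drive"})

    def test_no_component_baseline_trains(self, small_study):
        """With every switch off the model reduces to fingerprint and
        expression MLPs and still trains."""
        ds, _ = small_study
        cfg = ModelConfig(latent=16, modality_hidden=32, pred_hidden=(32,),
                          epochs=3, batch_size=None)
        fit = SynergyModel(ds, config=cfg, switches=frozenset()).fit()
        assert np.isfinite(fit.loss_history).all()
        assert fit.network.h_dim == 0

    def test_summary_mentions_components(self, small_fit):
        text = small_fit.summary()
        assert "molecular_gcn" in text and "train records" in text


@pytest.fixture(scope="module")
def cv(small_study):
    ds, _ = small_study
    cfg = ModelConfig(d=8, latent=16, modality_hidden=32, pred_hidden=(32,),
                      mol_layers=(16, 16), epochs=4, batch_size=None)
    return SynergyModel(ds, config=cfg).fit_cv(k=3, seed=0)


class TestCrossValidation:
    def test_every_record_predicted_once(self, cv, small_study):
        ds, _ = small_study
        assert len(cv.predictions) == len(ds.records)
        assert set(cv.predictions["fold"]) == {0, 1, 2}

    def test_metrics_finite_and_coherent(self, cv):
        df = cv.metrics_frame()
        assert np.isfinite(df[["mse", "rmse", "pcc"]]).all().all()
        np.testing.assert_allclose(df["rmse"], np.sqrt(df["mse"]), atol=1e-12)

    def test_no_test_edge_leaks_into_training_graph(self, cv, small_study):
        """Graphs of each fold contain no edge for any held-out pair."""
        ds, _ = small_study
        model = cv.model
        for fold, fit in enumerate(cv.fits):
            _, test = cv.folds.train_test(fold)
            tensors = fit.ctx.tensors
            for t in test:
                i, j, r = model.triplets[t]
                assert not tensors[r][i, j, :].any()

    def test_per_cell_line_table(self, cv, small_study):
        ds, _ = small_study
        table = cv.per_cell_line()
        assert set(table.index) == set(ds.cell_lines)
        assert (table["n"] > 0).all()

    def test_summary_renders(self, cv):
        text = cv.summary()
        assert "PCC" in text and "CI95" in text
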
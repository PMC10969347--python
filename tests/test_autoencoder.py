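"""Autoencoder surface: split, encode/decode, losses, training behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nasalrecon as nr
from nasalrecon import autoencoder as ae
from nasalrecon import nn
from nasalrecon.mesh_core import MeshTopologyError


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(400, (340, 40, 20)), (40, (34, 4, 2)), (60, (51, 6, 3))],
    )
    def test_ratio_17_2_1_sizes(self, n, expected):
        tr, va, te = ae.split_dataset(n, (17, 2, 1), seed=0)
        assert (len(tr), len(va), len(te)) == expected

    def test_disjoint_exhaustive_and_seeded(self):
        tr, va, te = ae.split_dataset(57, seed=4)
        tr2, va2, te2 = ae.split_dataset(57, seed=4)
        assert np.array_equal(tr, tr2) and np.array_equal(va, va2) and np.array_equal(te, te2)
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == 57
        assert len(set(allidx)) == 57

    def test_different_seed_different_split(self):
        tr1, _, _ = ae.split_dataset(60, seed=0)
        tr2, _, _ = ae.split_dataset(60, seed=1)
        assert not np.array_equal(tr1, tr2)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            ae.split_dataset(19)


class TestLosses:
    def test_recon_zero_iff_identical(self, template):
        m = template.mesh
        assert ae.recon_loss(m, m) == 0.0
        shifted = m.with_vertices(m.vertices + [1.0, 0.0, 0.0])
        assert ae.recon_loss(m, shifted) == pytest.approx(1.0, abs=1e-12)

    def test_recon_symmetric(self, template):
        rng = np.random.default_rng(0)
        a = template.mesh.with_vertices(template.mesh.vertices + rng.normal(size=(template.mesh.n_vertices, 3)))
        b = template.mesh
        assert ae.recon_loss(a, b) == pytest.approx(ae.recon_loss(b, a), rel=1e-12)

    def test_recon_matches_independent_recomputation(self, template):
        rng = np.random.default_rng(7)
        v1 = template.mesh.vertices + rng.normal(size=(template.mesh.n_vertices, 3))
        v2 = template.mesh.vertices + rng.normal(size=(template.mesh.n_vertices, 3))
        a, b = template.mesh.with_vertices(v1), template.mesh.with_vertices(v2)
        # oracle: plain python double-precision loop
        total = 0.0
        for p, q in zip(v1, v2):
            total += (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
        assert ae.recon_loss(a, b) == pytest.approx(total / len(v1), rel=1e-12)

    def test_recon_topology_mismatch(self, template, template_small):
        with pytest.raises(MeshTopologyError):
            ae.recon_loss(template.mesh, template_small.mesh)

    @pytest.mark.parametrize(
        "norm,expected", [(1.0, 0.0), (0.0, 1.0), (3.0, 4.0)]
    )
    def test_reg_loss_values(self, norm, expected):
        z = np.zeros(16)
        z[0] = norm
        assert ae.reg_loss(z) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_total_loss_arithmetic_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, 3))
        xh = rng.normal(size=(30, 3))
        z = rng.normal(size=8)
        lam = float(rng.uniform(0, 1))
        lhs = ae.total_loss(x, xh, z, lam)
        rhs = ae.recon_loss(x, xh) + lam * ae.reg_loss(z)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_lambda_zero_reduces_to_recon(self):
        rng = np.random.default_rng(1)
        x, xh, z = rng.normal(size=(9, 3)), rng.normal(size=(9, 3)), rng.normal(size=4)
        assert ae.total_loss(x, xh, z, 0.0) == ae.recon_loss(x, xh)


class TestEncodeDecode:
    def test_encode_shape_and_determinism(self, init_params, graph, template):
        z1 = ae.encode(init_params, graph, template.mesh)
        z2 = ae.encode(init_params, graph, template.mesh)
        assert z1.shape == (32,)
        assert np.isfinite(z1).all()
        assert np.array_equal(z1, z2)

    def test_decode_shape_and_determinism(self, init_params, graph, template):
        z = np.random.default_rng(0).standard_normal(32)
        m1 = ae.decode(init_params, graph, z)
        m2 = ae.decode(init_params, graph, z)
        assert m1.n_vertices == template.mesh.n_vertices
        assert np.array_equal(m1.faces, template.mesh.faces)
        assert np.array_equal(m1.vertices, m2.vertices)

    def test_decode_dimension_mismatch(self, init_params, graph):
        with pytest.raises(ValueError):
            ae.decode(init_params, graph, np.zeros(31))

    def test_encode_topology_mismatch(self, init_params, graph, template_small):
        with pytest.raises(MeshTopologyError):
            ae.encode(init_params, graph, template_small.mesh)

    def test_decoder_gradient_matches_finite_differences(self, init_params, graph):
        """Analytic d(mean vertex x)/dz vs central differences."""
        cfg = init_params.config
        ops = graph._nn_ops
        rng = np.random.default_rng(5)
        z = rng.standard_normal(cfg.latent_dim)
        n = init_params.ref_vertices.shape[0]
        dOut = np.zeros((1, n, 3))
        dOut[0, :, 0] = 1.0 / n  # gradient of mean x-coordinate
        out, cache = nn.decoder_forward(init_params.weights, ops, cfg, z[None])
        _, dZ = nn.decoder_backward(init_params.weights, ops, cfg, cache, dOut)
        eps = 1e-5
        for i in range(0, cfg.latent_dim, 7):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            op, _ = nn.decoder_forward(init_params.weights, ops, cfg, zp[None])
            om, _ = nn.decoder_forward(init_params.weights, ops, cfg, zm[None])
            num = (op[0, :, 0].mean() - om[0, :, 0].mean()) / (2 * eps)
            assert num == pytest.approx(dZ[0, i], rel=1e-4, abs=1e-10)


class TestTraining:
    def test_loss_decreases_and_capacity(self, trained, population_model):
        params, history = trained
        assert history["train_recon"][-1] < history["train_recon"][0]
        # capacity: D=32 >= population rank 8 on noiseless low-rank data
        assert history["val_recon"][-1] < 0.1 * population_model.mean_vertex_variance()

    def test_latent_norms_drawn_toward_unit_sphere(self, trained):
        _, history = trained
        assert history["z_norm_dev"][-1] < history["z_norm_dev"][0]

    def test_smoothed_loss_settles_late_in_training(self, trained):
        """Over the final half of training the 5-epoch moving average shows
        no sustained increase (mini-batch descent wiggles, so exact
        monotonicity is not expected) and finishes at its minimum."""
        _, history = trained
        tr = np.array(history["train_total"])
        kernel = np.ones(5) / 5
        smooth = np.convolve(tr, kernel, mode="valid")
        half = smooth[len(smooth) // 2 :]
        running_min = np.minimum.accumulate(half)
        assert np.all(half <= 1.3 * running_min + 1e-9)  # bounded transients only
        assert half[-1] == pytest.approx(half.min(), rel=1e-9)

    def test_test_mse_on_training_members_is_small(self, trained, graph, population):
        """Reconstruction of training members (a deliberately overfit
        'test set') beats the held-out validation error and the 10%-of-
        variance capacity bar; note the returned weights are the best-
        validation epoch's, not the last epoch's."""
        params, history = trained
        train_ids = history["split"]["train"][:8]
        mse = ae.test_mse(params, graph, [population[i] for i in train_ids])
        assert mse < min(history["val_recon"])

    def test_default_hyperparameters(self):
        cfg = ae.TrainConfig()
        assert cfg.lambda_reg == 0.01
        assert cfg.learning_rate == 0.001
        assert cfg.split_ratio == (17, 2, 1)
        assert nn.ModelConfig().latent_dim == 256

    def test_checkpoint_roundtrip(self, trained, graph, template, tmp_path):
        params, _ = trained
        path = tmp_path / "model.npz"
        ae.save_checkpoint(path, params)
        again = ae.load_checkpoint(path)
        z = np.random.default_rng(3).standard_normal(params.latent_dim)
        m1 = ae.decode(params, graph, z)
        m2 = ae.decode(again, graph, z)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert again.topology_id == params.topology_id
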
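"""Loss formulas: closed forms, momentum updates, batch invariances."""

import numpy as np
import pytest

from interanimal import losses as L


def _unit(v):
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


class TestCrossEntropy:
    def test_uniform_logits_give_log_c(self):
        for c in (4, 10, 1000):
            loss = L.cross_entropy_loss(np.zeros((3, c)),
                                        np.array([0, 1, c - 1]) % c)
            assert loss == pytest.approx(np.log(c), abs=1e-12)

    def test_confident_correct_prediction_near_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        assert L.cross_entropy_loss(logits, [0]) < 1e-12

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            L.cross_entropy_loss(np.zeros((2, 5)), [0, 5])


class TestSparseAutoencoder:
    def test_perfect_reconstruction_zero_embedding(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        assert L.sparse_autoencoder_loss(img, img, np.zeros(128)) == 0.0

    def test_hand_oracle_case(self):
        # f(x) = x + 1 elementwise, ||v||_1 = 128, lambda = 0.0005:
        # 64^2 / (2 * 64^2) + 0.0005 * 128 / 128 = 0.5005
        img = np.zeros((64, 64))
        loss = L.sparse_autoencoder_loss(img + 1.0, img, np.ones(128),
                                         lam=0.0005)
        assert loss == pytest.approx(0.5 + 0.0005, abs=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            L.sparse_autoencoder_loss(np.zeros((8, 8)), np.zeros((8, 8)),
                                      np.zeros(4), lam=-0.1)


class TestDepthLoss:
    def test_prediction_equal_to_normalised_target_is_zero(self, rng):
        depth = rng.uniform(size=(32, 32))
        norm = (depth - depth.mean()) / depth.std()
        assert L.depth_mse_loss(norm, depth) == pytest.approx(0.0, abs=1e-12)

    def test_constant_depth_map_rejected(self):
        with pytest.raises(ValueError):
            L.depth_mse_loss(np.zeros((8, 8)), np.ones((8, 8)))


class TestMemoryBankInstanceRecognition:
    def test_bank_update_fixed_point(self, rng):
        vecs = _unit(rng.normal(size=(10, 16)))
        bank = L.MemoryBank(vecs.copy())
        bank.update([3], vecs[3][None])
        assert np.allclose(bank.vectors[3], vecs[3], atol=1e-12)

    def test_momentum_update_halves_distance_before_renorm(self, rng):
        # v <- 0.5 v + 0.5 z converges geometrically toward z (ratio 0.5)
        v = _unit(rng.normal(size=16))
        z = _unit(rng.normal(size=16))
        d0 = np.linalg.norm(0.5 * v + 0.5 * z - z)
        assert d0 == pytest.approx(0.5 * np.linalg.norm(v - z), abs=1e-12)
        d1 = np.linalg.norm(0.5 * (0.5 * v + 0.5 * z) + 0.5 * z - z)
        assert d1 == pytest.approx(0.25 * np.linalg.norm(v - z), abs=1e-12)

    def test_loss_decreases_as_embedding_approaches_bank_entry(self, rng):
        vecs = _unit(rng.normal(size=(64, 16)))
        bank = L.MemoryBank(vecs.copy())
        v = bank.vectors[0]
        start = _unit(rng.normal(size=16))
        path_losses = []
        z_const = None
        for t in np.linspace(0.0, 1.0, 10):
            z = _unit((1 - t) * start + t * v)[None]
            loss, z_const = L.instance_recognition_loss(
                z, [0], bank, n_negatives=16, partition_z=z_const, seed=4)
            path_losses.append(loss)
        # decreasing along the path; the negative term may fluctuate by a
        # hair once the positive term has saturated
        assert path_losses[-1] < path_losses[0]
        assert np.all(np.diff(path_losses) < 0.01)
        assert np.all(np.diff(path_losses[:6]) < 0.0)

    def test_explicit_partition_constant_respected(self, rng):
        vecs = _unit(rng.normal(size=(8, 4)))
        bank = L.MemoryBank(vecs.copy())
        z = vecs[:1]
        l1, z1 = L.instance_recognition_loss(z, [0], bank, n_negatives=4,
                                             partition_z=50.0, seed=0)
        assert z1 == 50.0

    def test_too_many_negatives_rejected(self, rng):
        bank = L.MemoryBank(_unit(rng.normal(size=(4, 4))))
        with pytest.raises(ValueError):
            L.instance_recognition_loss(bank.vectors[:1], [0], bank,
                                        n_negatives=10)


class TestMoco:
    def test_orthogonal_queue_closed_form(self):
        # v == k0, 8 orthogonal negatives, tau = 0.2:
        # loss = -log( e^5 / (e^5 + 8) )
        d = 16
        eye = np.eye(d)
        v = eye[:1]
        queue = L.EmbeddingQueue(eye[1:9])
        expected = -np.log(np.exp(5.0) / (np.exp(5.0) + 8.0))
        assert L.moco_loss(v, v, queue, tau=0.2) == pytest.approx(
            expected, abs=1e-12)

    def test_queue_fifo_semantics(self, rng):
        keys = _unit(rng.normal(size=(6, 4)))
        q = L.EmbeddingQueue(keys.copy())
        new = _unit(rng.normal(size=(2, 4)))
        q.enqueue_dequeue(new)
        assert len(q) == 6
        assert np.allclose(q.keys[-2:], new)
        assert np.allclose(q.keys[:4], keys[2:])

    def test_momentum_update_rule_exact(self, rng):
        tk = rng.normal(size=20)
        tq = rng.normal(size=20)
        out = L.momentum_update(tk, tq, momentum=0.999)
        assert np.allclose(out, 0.999 * tk + 0.001 * tq, atol=1e-15)

    def test_empty_queue_rejected(self, rng):
        with pytest.raises(ValueError):
            L.EmbeddingQueue(np.zeros((0, 4)))


class TestSimclr:
    def test_identical_embeddings_closed_form(self):
        for n in (2, 4, 8):
            z = np.tile(np.eye(16)[0], (n, 1))
            assert L.simclr_loss(z, z) == pytest.approx(
                np.log(2 * n - 1), abs=1e-10)

    def test_batch_size_one_rejected(self):
        with pytest.raises(ValueError):
            L.simclr_loss(np.ones((1, 4)), np.ones((1, 4)))

    def test_permutation_invariant_over_pairs(self, rng):
        z1 = _unit(rng.normal(size=(6, 8)))
        z2 = _unit(rng.normal(size=(6, 8)))
        perm = rng.permutation(6)
        assert L.simclr_loss(z1, z2) == pytest.approx(
            L.simclr_loss(z1[perm], z2[perm]), abs=1e-12)


class TestSimsiam:
    def test_aligned_unit_vectors_reach_lower_bound(self):
        z = np.tile(np.eye(8)[0], (4, 1))
        assert L.simsiam_loss(z, z, z, z) == pytest.approx(-1.0, abs=1e-12)

    def test_value_within_cosine_bounds(self, rng):
        blocks = [rng.normal(size=(5, 8)) for _ in range(4)]
        val = L.simsiam_loss(*blocks)
        assert -1.0 <= val <= 1.0

    def test_permutation_invariant(self, rng):
        blocks = [rng.normal(size=(5, 8)) for _ in range(4)]
        perm = rng.permutation(5)
        assert L.simsiam_loss(*blocks) == pytest.approx(
            L.simsiam_loss(*[b[perm] for b in blocks]), abs=1e-12)


class TestBarlowTwins:
    def test_whitened_identical_views_zero_loss(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(12, 8)))
        # orthonormal columns: cross-correlation matrix is exactly identity
        loss = L.barlow_twins_loss(q, q)
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_loss_nonnegative(self, rng):
        z1 = rng.normal(size=(10, 6))
        z2 = rng.normal(size=(10, 6))
        assert L.barlow_twins_loss(z1, z2) >= 0.0

    def test_permutation_invariant(self, rng):
        z1 = rng.normal(size=(10, 6))
        z2 = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        assert L.barlow_twins_loss(z1, z2) == pytest.approx(
            L.barlow_twins_loss(z1[perm], z2[perm]), abs=1e-12)


class TestVicreg:
    def test_identical_spread_views_have_small_loss(self, rng):
        # high-variance, decorrelated, identical views: all three terms ~ 0
        q, _ = np.linalg.qr(rng.normal(size=(32, 8)))
        z = q * np.sqrt(32) * 1.3  # per-dimension std safely above 1
        assert L.vicreg_loss(z, z) < 0.1

    def test_collapsed_embeddings_penalised(self):
        z = np.ones((16, 8))
        assert L.vicreg_loss(z, z) > 10.0

    def test_permutation_invariant(self, rng):
        z1 = rng.normal(size=(10, 6))
        z2 = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        assert L.vicreg_loss(z1, z2) == pytest.approx(
            L.vicreg_loss(z1[perm], z2[perm]), abs=1e-10)
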
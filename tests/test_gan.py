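"""Combination operation, loss functions, gradient penalty, GAN contracts."""

import numpy as np
import pytest

from fetalmsp import autodiff as ad
from fetalmsp import gan, nn
from fetalmsp.autodiff import Tensor


class TestCombine:
    def test_two_channel_output(self, rng):
        m = rng.random((6, 6, 6))
        v = rng.random((6, 6, 6))
        out = gan.combine(m, v)
        assert out.shape == (2, 6, 6, 6)

    def test_identity_mask(self, rng):
        v = rng.random((4, 4, 4))
        out = gan.combine(np.ones_like(v), v)
        assert np.array_equal(out[0], out[1])

    def test_zero_mask(self, rng):
        v = rng.random((4, 4, 4))
        out = gan.combine(np.zeros_like(v), v)
        assert np.all(out[0] == 0)
        assert np.array_equal(out[1], v)

    def test_tensor_path_matches_numpy(self, rng):
        m = rng.random((2, 1, 4, 4, 4)).astype(np.float32)
        v = rng.random((2, 1, 4, 4, 4)).astype(np.float32)
        t = gan.combine(Tensor(m), Tensor(v))
        assert t.shape == (2, 2, 4, 4, 4)
        assert np.allclose(t.data[:, 0], m[:, 0] * v[:, 0])
        assert np.allclose(t.data[:, 1], v[:, 0])

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            gan.combine(rng.random((3, 3, 3)), rng.random((4, 4, 4)))


class TestCrossEntropy:
    def test_perfect_prediction_is_tiny(self):
        y = (np.random.default_rng(0).random((5, 5, 5)) > 0.5).astype(float)
        assert gan.cross_entropy(y, y) <= 1e-6

    def test_uniform_half_is_ln2(self, rng):
        y = (rng.random((6, 6, 6)) > 0.3).astype(float)
        x = np.full_like(y, 0.5)
        assert np.isclose(gan.cross_entropy(x, y), np.log(2), atol=1e-7)

    def test_monotone_in_wrongness(self, rng):
        y = (rng.random((6, 6, 6)) > 0.5).astype(float)
        xs = [np.abs(y - e) for e in (0.1, 0.3, 0.5)]
        vals = [gan.cross_entropy(x, y) for x in xs]
        assert vals[0] < vals[1] < vals[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gan.cross_entropy(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGeneratorLoss:
    def setup_method(self):
        r = np.random.default_rng(1)
        self.x = r.random((2, 1, 4, 4, 4)).astype(np.float32)
        self.y = (r.random((2, 1, 4, 4, 4)) > 0.5).astype(np.float32)
        self.c = r.random((2, 3)).astype(np.float32)

    def test_w1_reduces_to_cross_entropy(self):
        lw = gan.LossWeights(w=1.0)
        assert np.isclose(
            gan.generator_loss(self.c, self.x, self.y, lw),
            gan.cross_entropy(self.x, self.y),
            atol=1e-7,
        )

    def test_w0_reduces_to_negative_critic_mean(self):
        lw = gan.LossWeights(w=0.0)
        assert np.isclose(
            gan.generator_loss(self.c, self.x, self.y, lw), -self.c.mean(), atol=1e-7
        )

    def test_two_term_composition_at_default_weight(self):
        lw = gan.LossWeights(w=0.8)
        m = self.c.mean()
        ce = gan.cross_entropy(self.x, self.y)
        assert np.isclose(
            gan.generator_loss(self.c, self.x, self.y, lw),
            0.2 * (-m) + 0.8 * ce,
            atol=1e-6,
        )

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            gan.LossWeights(w=1.5)


class _UnitLipschitzCritic:
    """C(x) = sum(x) / sqrt(n elements): input gradient norm is exactly 1."""

    def __call__(self, x):
        n = x.size // x.shape[0]
        flat = ad.reshape(x, (x.shape[0], -1))
        w = Tensor(np.full((n, 1), 1.0 / np.sqrt(n), dtype=np.float32))
        return ad.matmul(flat, w)


class _ConstantCritic:
    def __call__(self, x):
        z = ad.mul(ad.astensor(np.float32(0.0)),
                   ad.mean_(ad.reshape(x, (x.shape[0], -1)), axis=1, keepdims=True))
        return ad.add(z, ad.astensor(np.float32(3.0)))


class TestGradientPenalty:
    def test_unit_lipschitz_gives_zero(self, rng):
        x = rng.random((4, 2, 8, 8, 8)).astype(np.float32)
        assert abs(gan.gradient_penalty(_UnitLipschitzCritic(), x).item()) < 1e-5

    def test_constant_critic_gives_one(self, rng):
        x = rng.random((4, 2, 8, 8, 8)).astype(np.float32)
        assert abs(gan.gradient_penalty(_ConstantCritic(), x).item() - 1.0) < 1e-5

    def test_interpolation_endpoints(self, rng):
        x = rng.random((3, 1, 4, 4, 4)).astype(np.float32)
        y = (rng.random((3, 1, 4, 4, 4)) > 0.5).astype(np.float32)
        for alpha, expected in ((0.0, x), (1.0, y)):
            xhat = alpha * y + (1 - alpha) * x
            assert np.array_equal(xhat, expected)


class TestCriticLoss:
    def test_zero_when_fake_equals_real_without_penalty(self, rng):
        critic = gan.Critic(gan.scaled_critic_config(), 32, rng)
        v = rng.random((2, 1, 32, 32, 32)).astype(np.float32)
        y = (rng.random((2, 1, 32, 32, 32)) > 0.9).astype(np.float32)
        xp = gan.combine(Tensor(y), Tensor(v))
        lw = gan.LossWeights(lam=0.0)
        loss = gan.critic_loss(critic, xp, xp, xp, lw)
        assert abs(loss.item()) < 1e-6

    def test_lambda_zero_is_wasserstein_surrogate(self, rng):
        critic = gan.Critic(gan.scaled_critic_config(), 32, rng)
        v = rng.random((2, 1, 32, 32, 32)).astype(np.float32)
        x = rng.random((2, 1, 32, 32, 32)).astype(np.float32)
        y = (rng.random((2, 1, 32, 32, 32)) > 0.9).astype(np.float32)
        xp = gan.combine(Tensor(x), Tensor(v))
        yp = gan.combine(Tensor(y), Tensor(v))
        lw = gan.LossWeights(lam=0.0)
        loss = gan.critic_loss(critic, xp, yp, xp, lw)
        with ad.no_grad():
            fake = critic(xp).data.mean()
            real = critic(yp).data.mean()
        assert np.isclose(loss.item(), fake - real, atol=1e-6)

    def test_term_wise_composition(self, rng):
        critic = gan.Critic(gan.scaled_critic_config(), 32, rng)
        v = rng.random((2, 1, 32, 32, 32)).astype(np.float32)
        x = rng.random((2, 1, 32, 32, 32)).astype(np.float32)
        y = (rng.random((2, 1, 32, 32, 32)) > 0.9).astype(np.float32)
        alpha = rng.uniform(0, 1, (2, 1, 1, 1, 1)).astype(np.float32)
        xhat = alpha * y + (1 - alpha) * x
        xp = gan.combine(Tensor(x), Tensor(v))
        yp = gan.combine(Tensor(y), Tensor(v))
        xhp = gan.combine(Tensor(xhat), Tensor(v))
        lw = gan.LossWeights(lam=10.0)
        loss = gan.critic_loss(critic, xp, yp, xhp, lw)
        with ad.no_grad():
            fake = critic(xp).data.mean()
            real = critic(yp).data.mean()
        gp = gan.gradient_penalty(critic, xhp).item()
        assert np.isclose(loss.item(), fake - real + 10.0 * gp, atol=1e-5)


class TestTrainPredictContracts:
    def test_one_step_smoke_and_determinism(self, rng):
        vols = [rng.random((32, 32, 32)).astype(np.float32) for _ in range(4)]
        masks = [(rng.random((32, 32, 32)) > 0.97).astype(np.float32) for _ in range(4)]
        runs = []
        for _ in range(2):
            gen, critic, hist = gan.train_gan(
                vols, masks, gan.scaled_generator_config(), gan.scaled_critic_config(),
                epochs=2, batch_size=4, seed=7,
            )
            assert np.isfinite(hist.generator_loss).all()
            assert np.isfinite(hist.critic_loss).all()
            for p in gen.parameters() + critic.parameters():
                assert np.isfinite(p.data).all()
            runs.append((hist.generator_loss, hist.critic_loss))
        assert runs[0] == runs[1]

    def test_predict_mask_shape_range_and_size_check(self, rng):
        vols = [rng.random((32, 32, 32)).astype(np.float32) for _ in range(2)]
        masks = [(rng.random((32, 32, 32)) > 0.97).astype(np.float32) for _ in range(2)]
        gen, _, _ = gan.train_gan(
            vols, masks, gan.scaled_generator_config(), gan.scaled_critic_config(),
            epochs=1, batch_size=2, seed=0,
        )
        m = gan.predict_mask(gen, vols[0])
        assert m.shape == vols[0].shape
        assert m.min() >= 0.0 and m.max() <= 1.0
        with pytest.raises(ValueError):
            gan.predict_mask(gen, np.zeros((16, 16, 16), np.float32))

    def test_mismatched_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            gan.train_gan([rng.random((32, 32, 32))], [rng.random((16, 16, 16))])
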
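"""Loss-term arithmetic, stop-gradient routing, center management, training."""

import numpy as np
import pytest

from vqsvdd.autograd import Tensor
from vqsvdd.errors import ConfigurationError, StateError
from vqsvdd.metrics import MsSsimParams
from vqsvdd.model import ArchitectureConfig, VqSvddModel
from vqsvdd.phantom import (AnomalySpec, PhantomConfig,
                            generate_normal_volume, inject_anomaly)
from vqsvdd.training import (HypersphereState, TrainConfig, initialize_center,
                             loss_step1, loss_step2, loss_step3, train,
                             update_center)

TINY = ArchitectureConfig.tiny(64, seed=0)
MS = MsSsimParams(window="uniform", window_size=3, M=1)


@pytest.fixture(scope="module")
def model():
    return VqSvddModel(TINY)


@pytest.fixture
def batch(rng):
    return Tensor(rng.random((2, 1, 64, 64)))


class TestLossArithmetic:
    def test_stage1_total_is_weighted_sum(self, model, batch):
        bundle = model.forward(batch, bypass=True)
        total, bd = loss_step1(batch, bundle, lam=0.25, msssim=MS)
        assert total.item() == pytest.approx(bd.total, rel=1e-12)
        assert bd.consistency_term is None and bd.svdd_term is None
        for v in (bd.recon_l2, bd.msssim_term, bd.codebook_term,
                  bd.commit_term):
            assert v >= 0.0
        # commit term carries the lambda weight: raw norms satisfy
        # codebook_term = commit_term / lambda in bypass mode (z_d = z_e)
        assert bd.commit_term == pytest.approx(0.25 * bd.codebook_term,
                                               rel=1e-9)

    def test_stage2_adds_consistency(self, model, batch):
        bundle = model.forward(batch)
        t2, bd2 = loss_step2(batch, bundle, lam=0.25, msssim=MS)
        assert bd2.consistency_term is not None and bd2.consistency_term >= 0
        assert t2.item() == pytest.approx(bd2.total, rel=1e-12)

    def test_consistency_squared_norm_arithmetic(self, model, batch):
        bundle = model.forward(batch)
        _, bd = loss_step2(batch, bundle, lam=0.25, msssim=MS)
        diff = bundle.z_e.data - bundle.z_d.data
        per_image = (diff ** 2).sum() / diff.shape[0]
        assert bd.consistency_term == pytest.approx(per_image, rel=1e-12)

    def test_stage3_adds_svdd_distance(self, model, batch):
        bundle = model.forward(batch)
        center = bundle.z.data.mean(axis=0)
        sphere = HypersphereState(center=center)
        t3, bd3 = loss_step3(batch, bundle, sphere, lam=0.25, msssim=MS)
        _, bd2 = loss_step2(batch, bundle, lam=0.25, msssim=MS)
        assert bd3.svdd_term >= 0.0
        assert t3.item() == pytest.approx(bd2.total + bd3.svdd_term, rel=1e-9)
        # z exactly at the center: the term vanishes
        z0 = bundle.z.data[0:1]
        sphere0 = HypersphereState(center=z0[0])
        svdd = ((bundle.z.data[0] - sphere0.center) ** 2).sum()
        assert svdd == pytest.approx(0.0)

    def test_two_dim_svdd_distance_value(self):
        z = np.array([0.3, 0.4])
        assert ((z - np.zeros(2)) ** 2).sum() == pytest.approx(0.25)

    def test_stage3_requires_center(self, model, batch):
        bundle = model.forward(batch)
        with pytest.raises(StateError):
            loss_step3(batch, bundle, HypersphereState(), msssim=MS)

    def test_stage_mode_mismatch_rejected(self, model, batch):
        full = model.forward(batch)
        bypass = model.forward(batch, bypass=True)
        with pytest.raises(ConfigurationError):
            loss_step1(batch, full, msssim=MS)
        with pytest.raises(ConfigurationError):
            loss_step2(batch, bypass, msssim=MS)


class TestStopGradientRouting:
    """Audit of the sg operator in the codebook / commitment terms."""

    def test_codebook_term_reaches_only_codebook(self, model, batch):
        bundle = model.forward(batch, bypass=True)
        for p in model.parameters():
            p.grad = None
        n = batch.shape[0]
        codebook_term = ((bundle.z_d.detach() - bundle.e_sel) ** 2).sum() * (1 / n)
        codebook_term.backward()
        assert model.codebook.vectors.grad is not None
        assert np.abs(model.codebook.vectors.grad).max() > 0
        for p in model.encoder1.parameters():
            assert p.grad is None

    def test_commit_term_reaches_only_encoder(self, model, batch):
        bundle = model.forward(batch, bypass=True)
        for p in model.parameters():
            p.grad = None
        n = batch.shape[0]
        commit = ((bundle.z_d - bundle.e_sel.detach()) ** 2).sum() * (0.25 / n)
        commit.backward()
        assert model.codebook.vectors.grad is None
        enc_grads = [p.grad for p in model.encoder1.parameters()]
        assert any(g is not None and np.abs(g).max() > 0 for g in enc_grads)

    def test_perturbing_codebook_row_changes_codebook_term_only_and_not_encoder_grad(
            self, model, batch):
        # finite-difference audit: a codebook perturbation moves the
        # codebook term but leaves the encoder gradient of the commit term
        # unchanged when the selected entries stay the same
        bundle = model.forward(batch, bypass=True)
        _, bd = loss_step1(batch, bundle, lam=0.25, msssim=MS)

        def encoder_grad_of_commit():
            for p in model.parameters():
                p.grad = None
            b = model.forward(batch, bypass=True)
            n = batch.shape[0]
            (((b.z_d - b.e_sel.detach()) ** 2).sum() * (0.25 / n)).backward()
            some = next(iter(model.encoder1.parameters()))
            return some.grad.copy(), b.indices

        g0, idx0 = encoder_grad_of_commit()
        eps = 1e-7  # small enough not to flip any nearest-neighbour choice
        model.codebook.vectors.data[0, 0] += eps
        try:
            b1 = model.forward(batch, bypass=True)
            _, bd1 = loss_step1(batch, b1, lam=0.25, msssim=MS)
            g1, idx1 = encoder_grad_of_commit()
        finally:
            model.codebook.vectors.data[0, 0] -= eps
        np.testing.assert_array_equal(idx0, idx1)
        if 0 in idx0:  # entry 0 selected somewhere: term must move
            assert bd1.codebook_term != bd.codebook_term
        np.testing.assert_allclose(g0, g1, atol=1e-12)


class TestCenterManagement:
    def test_initialize_center_is_latent_mean(self):
        cfg = PhantomConfig(image_size=64, seed=2)
        vols = [generate_normal_volume(cfg, i) for i in range(2)]
        model = VqSvddModel(TINY)
        sphere = initialize_center(model, vols, batch_size=16)
        slices = np.concatenate([v.slices for v in vols])
        expected = model.encode_latent(slices).mean(axis=0)
        np.testing.assert_allclose(sphere.center, expected, atol=1e-10)

    def test_streaming_mean_matches_two_pass(self, rng):
        latents = rng.normal(0, 1, (1000, 8))
        streaming = np.zeros(8)
        for row in latents:
            streaming += row
        streaming /= len(latents)
        np.testing.assert_allclose(streaming, latents.mean(axis=0), atol=1e-6)

    def test_update_center_replaces_not_averages(self):
        sphere = HypersphereState(center=np.zeros(3))
        epoch1 = np.tile([1.0, 2.0, 3.0], (5, 1))
        s1 = update_center(sphere, epoch1)
        np.testing.assert_allclose(s1.center, [1, 2, 3])
        epoch2 = np.tile([-1.0, 0.0, 1.0], (3, 1))
        s2 = update_center(s1, epoch2)
        np.testing.assert_allclose(s2.center, [-1, 0, 1])  # epoch-2 only
        assert s2.n_updates == 2

    def test_empty_epoch_warns_and_keeps_center(self):
        sphere = HypersphereState(center=np.ones(2), n_updates=3)
        with pytest.warns(UserWarning):
            s = update_center(sphere, np.empty((0, 2)))
        np.testing.assert_allclose(s.center, [1, 1])
        assert s.n_updates == 3

    def test_single_latent_center(self):
        model = VqSvddModel(TINY)
        cfg = PhantomConfig(image_size=64, slices_per_case=(1, 1), seed=5)
        vol = generate_normal_volume(cfg, 0)
        sphere = initialize_center(model, [vol])
        np.testing.assert_allclose(sphere.center,
                                   model.encode_latent(vol.slices)[0],
                                   atol=1e-10)


class TestTrainProtocol:
    def test_abnormal_volume_rejected(self):
        cfg = PhantomConfig(image_size=64, seed=3)
        bad = inject_anomaly(generate_normal_volume(cfg, 0),
                             AnomalySpec(kind="nodule", radius_px=5,
                                         intensity_delta=0.4), seed=0)
        with pytest.raises(ConfigurationError):
            train([bad], TINY, TrainConfig(max_epochs=0))

    def test_zero_epochs_is_noop(self):
        cfg = PhantomConfig(image_size=64, seed=3)
        vols = [generate_normal_volume(cfg, 0)]
        result = train(vols, TINY, TrainConfig(max_epochs=0, seed=0))
        fresh = VqSvddModel(TINY)
        for (k, a), (_, b) in zip(sorted(result.model.state_arrays().items()),
                                  sorted(fresh.state_arrays().items())):
            np.testing.assert_array_equal(a, b)
        assert result.history == []
        assert not result.sphere.initialized
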
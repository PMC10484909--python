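"""Federated training orchestration: privacy audit, single-center
equivalence, sampling distribution, determinism, continual contracts."""

import numpy as np
import pytest

from distsynth.datagen import (CenterSpec, PhantomSpec, TaskSequence,
                               make_center_data)
from distsynth.losses import LossWeights
from distsynth.trainer import (ALLOWED_KINDS, CenterNode, Channel, MaskSampler,
                               PrivacyError, TrainConfig, continual_train,
                               payload_hash, train, train_monolithic)


def _config(seed=0, **kw):
    base = dict(mode="base", epochs=2, rounds_per_epoch=3, batch_size=2,
                gen_base_width=4, gen_res_blocks=1, disc_width=4,
                eval_every=2, n_eval_samples=8, seed=seed,
                weights=LossWeights(lambda1=10.0, lambda2=0.0))
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture()
def federation(phantom):
    specs = [CenterSpec("A", 6, (0,), seed=1, intensity_shift=-0.1),
             CenterSpec("B", 4, (0,), seed=2),
             CenterSpec("C", 6, (0,), seed=3, intensity_shift=0.1)]
    return [make_center_data(s, phantom) for s in specs]


class TestChannel:
    def test_disallowed_payload_kind_aborts(self):
        ch = Channel()
        with pytest.raises(PrivacyError, match="not allowed"):
            ch.send("A->server", "real_image", np.zeros(4))

    def test_every_message_is_logged_with_hash(self):
        ch = Channel()
        ch.send("A->server", "mask", np.zeros(4, dtype=np.int32))
        ch.send("server->A", "synthetic_image", np.zeros(4))
        assert [r["kind"] for r in ch.log] == ["mask", "synthetic_image"]
        assert all(len(r["hash"]) == 64 for r in ch.log)


class TestTrainRun:
    def test_audit_log_contains_only_allowed_kinds(self, federation, phantom):
        res = train(_config(), federation, phantom)
        kinds = {r["kind"] for r in res.channel.log}
        assert kinds <= ALLOWED_KINDS
        assert {"mask", "synthetic_image", "gradient_packet",
                "loss_scalars", "feature_stats"} <= kinds

    def test_no_real_image_payload_ever_crosses_the_wire(self, federation,
                                                         phantom):
        from distsynth.datagen import to_tanh_range
        res = train(_config(), federation, phantom)
        real_hashes = set()
        for d in federation:
            for y in d.images:
                real_hashes.add(payload_hash(np.ascontiguousarray(y)))
                real_hashes.add(payload_hash(
                    np.ascontiguousarray(to_tanh_range(y))))
        sent = {r["hash"] for r in res.channel.log}
        assert not (sent & real_hashes)

    def test_same_seed_reproduces_loss_history(self, federation, phantom):
        h1 = train(_config(seed=4), federation, phantom).history
        h2 = train(_config(seed=4), federation, phantom).history
        assert h1["g_loss"] == h2["g_loss"]
        assert h1["dist_fid"] == h2["dist_fid"]

    def test_best_checkpoint_is_argmin_of_dist_fid(self, federation, phantom):
        res = train(_config(epochs=4, eval_every=1), federation, phantom)
        curve = res.history["dist_fid"]
        assert res.best_epoch == res.history["dist_fid_epoch"][
            int(np.argmin(curve))]

    def test_base_mode_rejects_incomplete_centers(self, phantom):
        spec2 = PhantomSpec(image_size=16, n_classes=2,
                            intensity_table=((0.1, 0.1), (0.4, 0.4),
                                             (0.7, 0.7)),
                            noise_sd=0.02)
        data = [make_center_data(CenterSpec("A", 4, (0,), seed=1), spec2),
                make_center_data(CenterSpec("B", 4, (0, 1), seed=2), spec2)]
        with pytest.raises(ValueError, match="complete modalities"):
            train(_config(), data, spec2)


class TestSingleCenterEquivalence:
    def test_one_center_run_matches_monolithic_conditional_gan(self, phantom):
        """With one center the distributed round must reproduce an ordinary
        conditional-GAN alternating update step-for-step (10 steps)."""
        data = [make_center_data(CenterSpec("A", 8, (0,), seed=5), phantom)]
        cfg = _config(seed=9, epochs=1, rounds_per_epoch=10, batch_size=2,
                      eval_every=10,
                      weights=LossWeights(lambda1=100.0, lambda2=10.0))
        res = train(cfg, data, phantom)
        mono, _ = train_monolithic(cfg, data[0], phantom, n_steps=10)
        for a, b in zip(res.generator.state(), mono.state()):
            assert np.abs(a - b).max() < 1e-5


class TestMaskSampler:
    def test_draw_frequencies_match_dataset_sizes(self, phantom):
        sizes = [30, 10, 20]
        data = [make_center_data(CenterSpec(f"c{i}", n, (0,), seed=i), phantom)
                for i, n in enumerate(sizes)]
        sampler = MaskSampler(data, np.random.default_rng(0))
        _, centers = sampler.sample(3000)
        freq = np.bincount(centers, minlength=3) / 3000
        expected = np.array(sizes) / sum(sizes)
        # binomial 99.9% envelope at n=3000
        se = np.sqrt(expected * (1 - expected) / 3000)
        assert np.all(np.abs(freq - expected) < 3.3 * se)


class TestMissingMode:
    def test_packets_cover_only_local_modalities(self):
        phantom = PhantomSpec(image_size=16, n_classes=1,
                              intensity_table=((0.1, 0.1), (0.5, 0.7)),
                              shape_params=((0.2, 0.3),), noise_sd=0.02)
        data = make_center_data(CenterSpec("A", 4, (0,), seed=1), phantom)
        cfg = _config(mode="missing")
        node = CenterNode(data, cfg, per_modality=True)
        idx, _ = node.sample_mask_batch(2)
        yhat = np.zeros((2, 1, 16, 16))
        raw = node.training_step(idx, yhat)
        from distsynth.losses import unpack_gradient_packet
        packet = unpack_gradient_packet(raw)
        assert packet.grad.shape == (2, 1, 16, 16)  # one channel, not two


class TestContinual:
    def _sequence(self, phantom):
        return TaskSequence((
            (0, [CenterSpec("T1", 6, (0,), seed=1, intensity_shift=-0.1)]),
            (1, [CenterSpec("T2", 6, (0,), seed=2, intensity_shift=0.1)]),
        ))

    def test_first_task_is_plain_training(self, phantom):
        seq = self._sequence(phantom)
        cfg = _config(mode="continual", seed=3)
        results = continual_train(seq, cfg, phantom)
        from distsynth.trainer import _derive
        solo_cfg = _config(mode="continual", seed=_derive(3, "task", 0))
        solo = train(solo_cfg, [make_center_data(seq.tasks[0][1][0], phantom)],
                     phantom)
        assert results[0].history["g_loss"] == solo.history["g_loss"]

    def test_retired_center_data_is_inaccessible(self, phantom, center_data):
        node = CenterNode(center_data, _config(), per_modality=False)
        node.retire()
        with pytest.raises(PrivacyError, match="retired"):
            node.sample_mask_batch(2)

    def test_reminding_leaves_previous_generator_frozen(self, phantom):
        seq = self._sequence(phantom)
        cfg = _config(mode="continual", seed=3,
                      weights=LossWeights(lambda1=10.0, lambda2=0.0,
                                          lambda_reminding=1.0))
        results = continual_train(seq, cfg, phantom)  # raises if mutated
        assert len(results) == 2
        assert results[1].history["reminding"][-1] >= 0.0
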
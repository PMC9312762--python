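"""Loss arithmetic, learning-rate schedule, duration refresh and the loop."""

import numpy as np
import pytest

from ssrnet._autograd import Tensor
from ssrnet.model import ModelConfig, ModelOutput, SSRNet
from ssrnet.synthdata import SynthSpec, generate_utterance
from ssrnet.toneme import build_inventory
from ssrnet.training import (
    TrainConfig,
    duration_refresh_policy,
    noam_lr,
    prepare_corpus,
    ssrnet_loss,
    train,
)

from conftest import toneme_accuracy


def manual_output(mel_pre, mel_post, d_hat, logits, recon):
    return ModelOutput(
        mel_pre=Tensor(mel_pre),
        mel_post=Tensor(mel_post),
        durations_pred=Tensor(d_hat),
        toneme_logits=Tensor(logits) if logits is not None else None,
        emg_recon=Tensor(recon) if recon is not None else None,
        hidden_regulated=Tensor(np.zeros((mel_post.shape[0], 1))),
    )


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        M, N = 4, 3
        Y = np.random.default_rng(0).standard_normal((M, 80))
        d = np.array([2, 1, 1])
        logits = np.full((M, 3), -1e4)
        labels = np.array([0, 1, 2, 1])
        logits[np.arange(M), labels] = 1e4  # probability ~1 on the true class
        x = np.random.default_rng(1).standard_normal((M, 355))
        out = manual_output(Y.copy(), Y.copy(), d.astype(float), logits, x.copy())
        lb = ssrnet_loss(out, Y, d, labels, x, TrainConfig())
        assert lb.total == pytest.approx(0.0, abs=1e-9)
        assert lb.mae_post == lb.mae_pre == lb.mse_duration == lb.mse_recon == 0.0

    def test_single_frame_hand_arithmetic(self):
        Y = np.array([[1.0, 3.0]])
        mel_pre = np.array([[0.0, 0.0]])
        mel_post = np.array([[2.0, 1.0]])
        d = np.array([1])
        d_hat = np.array([3.0])
        logits = np.array([[0.0, np.log(3.0)]])  # p(correct=1) = 3/4
        labels = np.array([1])
        x = np.array([[1.0, -1.0]])
        recon = np.array([[0.0, 0.0]])
        cfg = TrainConfig()
        out = ModelOutput(
            mel_pre=Tensor(mel_pre),
            mel_post=Tensor(mel_post),
            durations_pred=Tensor(d_hat),
            toneme_logits=Tensor(logits),
            emg_recon=Tensor(recon),
            hidden_regulated=Tensor(np.zeros((1, 1))),
        )
        lb = ssrnet_loss(out, Y, d, labels, x, cfg)
        assert lb.mae_post == pytest.approx(1.5)  # (|2-1|+|1-3|)/2
        assert lb.mae_pre == pytest.approx(2.0)  # (1+3)/2
        assert lb.mse_duration == pytest.approx(4.0)  # (3-1)^2
        assert lb.ce_toneme == pytest.approx(-np.log(0.75))
        assert lb.mse_recon == pytest.approx(1.0)  # (1+1)/2
        expected = 1.5 + 2.0 + 4.0 + 0.5 * (-np.log(0.75)) + 0.5 * 1.0
        assert lb.total == pytest.approx(expected, rel=1e-12)

    def test_zero_weights_drop_joint_terms(self):
        rng = np.random.default_rng(2)
        M, N = 5, 4
        Y = rng.standard_normal((M, 80))
        out = manual_output(
            rng.standard_normal((M, 80)),
            rng.standard_normal((M, 80)),
            rng.random(N),
            rng.standard_normal((M, 3)),
            rng.standard_normal((M, 355)),
        )
        d = np.array([2, 1, 1, 1])
        cfg = TrainConfig(lambda_tm=0.0, lambda_recons=0.0)
        lb = ssrnet_loss(out, Y, d, np.zeros(M, int), rng.standard_normal((M, 355)), cfg)
        assert lb.total == pytest.approx(lb.mae_post + lb.mae_pre + lb.mse_duration)

    def test_weighted_sum_identity_on_random_tensors(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            M, N = int(rng.integers(2, 9)), int(rng.integers(2, 6))
            out = manual_output(
                rng.standard_normal((M, 80)),
                rng.standard_normal((M, 80)),
                rng.random(N),
                rng.standard_normal((M, 4)),
                rng.standard_normal((M, 355)),
            )
            Y = rng.standard_normal((M, 80))
            d = np.ones(N, int)
            d[0] = M - N + 1
            labels = rng.integers(0, 4, M)
            x = rng.standard_normal((M, 355))
            cfg = TrainConfig()
            lb = ssrnet_loss(out, Y, d, labels, x, cfg)
            expected = (
                lb.mae_post
                + lb.mae_pre
                + lb.mse_duration
                + cfg.lambda_tm * lb.ce_toneme
                + cfg.lambda_recons * lb.mse_recon
            )
            assert lb.total == pytest.approx(expected, abs=1e-6)
            assert lb.total >= 0

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        out = manual_output(
            rng.standard_normal((3, 80)), rng.standard_normal((3, 80)),
            np.ones(2), None, None,
        )
        with pytest.raises(ValueError):
            ssrnet_loss(out, rng.standard_normal((4, 80)), np.ones(2, int), None, None, TrainConfig())


class TestNoamSchedule:
    def test_peak_at_warmup(self):
        lr = noam_lr(4000, 384, 4000)
        assert lr == pytest.approx(384**-0.5 * 4000**-0.5, rel=1e-12)

    def test_halving_ratio(self):
        assert noam_lr(8000, 384, 4000) / noam_lr(4000, 384, 4000) == pytest.approx(
            2**-0.5, rel=1e-12
        )

    def test_monotone_warmup_then_decay(self):
        lrs = [noam_lr(s, 384, 4000) for s in range(1, 12001, 50)]
        peak_idx = int(np.argmax(lrs))
        assert all(a < b for a, b in zip(lrs[:peak_idx], lrs[1 : peak_idx + 1]))
        assert all(a > b for a, b in zip(lrs[peak_idx:], lrs[peak_idx + 1 :]))

    def test_closed_form_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            step = int(rng.integers(1, 100000))
            dm = int(rng.integers(16, 1024))
            sw = int(rng.integers(1, 20000))
            assert noam_lr(step, dm, sw) == pytest.approx(
                dm**-0.5 * min(step**-0.5, step * sw**-1.5), rel=1e-12
            )

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            noam_lr(0)


class TestRefreshPolicy:
    @pytest.mark.parametrize(
        "epoch,expected",
        [
            (1, "use_initial"),
            (3, "use_initial"),
            (4, "use_initial"),
            (5, "refresh_with_refined_cost"),
            (7, "keep_cached"),
            (10, "refresh_with_refined_cost"),
            (11, "keep_cached"),
        ],
    )
    def test_stated_rule(self, epoch, expected):
        assert duration_refresh_policy(epoch, TrainConfig()) == expected

    def test_pure_function(self):
        cfg = TrainConfig()
        assert all(
            duration_refresh_policy(e, cfg) == duration_refresh_policy(e, cfg)
            for e in range(1, 30)
        )


class TestTrainingLoop:
    def test_empty_corpus_rejected(self):
        m = SSRNet(ModelConfig.tiny(inventory_size=2, seed=0))
        with pytest.raises(ValueError):
            train([], m, TrainConfig())

    def test_determinism_same_seed(self):
        spec = SynthSpec(seed=5)
        samples = [generate_utterance(spec, seed=200 + i) for i in range(3)]
        inv = build_inventory(sorted({s for u in samples for s in u.transcript}))
        logs = []
        for _ in range(2):
            prepped, _ = prepare_corpus(samples, inv)
            m = SSRNet(ModelConfig.tiny(inventory_size=len(inv), seed=0))
            _, log = train(prepped, m, TrainConfig(batch_size=3, step_w=200, max_epochs=6, seed=0))
            logs.append([e["train_total"] for e in log])
        assert logs[0] == logs[1]

    def test_refresh_preserves_target_length(self, corpus50, trained_tiny):
        from ssrnet.training import _refresh_durations

        model = trained_tiny["model"]
        for u in corpus50["train"][:5]:
            M = int(u.durations.sum())
            _refresh_durations(model, u, lambda_align=10.0)
            assert int(u.durations.sum()) == M

    def test_overfit_reduces_loss(self, overfit_run):
        log = overfit_run["log"]
        assert log[-1]["train_total"] <= 0.10 * log[0]["train_total"]

    def test_toneme_weight_ablation(self, corpus50, trained_tiny):
        """Dropping the toneme loss leaves the classification head untrained:
        the default-weight model decodes tonemes far better than a model
        trained identically but with the toneme term zeroed."""
        m0 = SSRNet(ModelConfig.tiny(inventory_size=len(corpus50["inventory"]), seed=0))
        tc = trained_tiny["train_cfg"]
        tc0 = TrainConfig(
            batch_size=tc.batch_size, step_w=tc.step_w, max_epochs=tc.max_epochs,
            seed=tc.seed, lambda_tm=0.0,
        )
        m0, _ = train(corpus50["train"], m0, tc0, val_corpus=corpus50["val"])
        acc_default = toneme_accuracy(trained_tiny["model"], corpus50["test"])
        acc_ablated = toneme_accuracy(m0, corpus50["test"])
        assert acc_default > acc_ablated + 0.2


class TestEndToEndRecovery:
    def test_heldout_toneme_accuracy(self, corpus50, trained_tiny):
        """A tiny model trained on 50 synthetic utterances should decode
        most non-silent frames of held-out utterances correctly."""
        acc = toneme_accuracy(trained_tiny["model"], corpus50["test"])
        assert acc >= 0.70

    def test_duration_predictor_tracks_targets(self, corpus50, trained_tiny):
        model = trained_tiny["model"]
        u = corpus50["train"][0]
        m_pred = int(model.infer_durations(u.X).sum())
        M = int(u.durations.sum())
        assert abs(m_pred - M) <= 0.2 * M
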
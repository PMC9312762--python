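"""Joint loss, learning-rate schedule and the training loop.

The joint objective combines five terms:

    L = MAE(mel_post, Y) + MAE(mel_pre, Y) + MSE(d_hat, d)
        + lambda_tm * CE(toneme_logits, tm) + lambda_recons * MSE(x_hat, x)

where Y is the vocal-mode mel target, d the ground-truth durations from
DTW, tm the frame-level toneme labels and x the vocal-mode EMG features.
The learning rate follows the Noam warmup-then-decay schedule
lr = d_model^-0.5 * min(step^-0.5, step * step_w^-1.5).

Ground-truth durations are bootstrapped from a plain EMG-feature DTW
before training, reused for the first four epochs, and refreshed every
five epochs with the refined cost that mixes in the model's own
unregulated mel predictions (weight lambda_align).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor
from .alignment import DurationSequence, dtw
from .containers import EmgFeatureSequence, MelSequence
from .model import ModelOutput, SSRNet

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "ssrnet_loss",
    "noam_lr",
    "duration_refresh_policy",
    "train",
]


@dataclass
class TrainConfig:
    batch_size: int = 8
    lambda_align: float = 10.0
    lambda_tm: float = 0.5
    lambda_recons: float = 0.5
    step_w: int = 4000
    d_model_schedule: int = 384
    duration_refresh_period: int = 5
    initial_plain_cost_epochs: int = 4
    max_epochs: int = 20
    grad_clip: float = 1.0
    lr_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lambda_align, self.lambda_tm, self.lambda_recons) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.step_w < 1:
            raise ValueError("warmup steps must be >= 1")


@dataclass
class LossBreakdown:
    mae_post: float
    mae_pre: float
    mse_duration: float
    ce_toneme: float
    mse_recon: float
    total: float
    total_tensor: Tensor | None = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "mae_post": self.mae_post,
            "mae_pre": self.mae_pre,
            "mse_duration": self.mse_duration,
            "ce_toneme": self.ce_toneme,
            "mse_recon": self.mse_recon,
            "total": self.total,
        }


def ssrnet_loss(
    out: ModelOutput,
    Y: MelSequence | np.ndarray,
    d: DurationSequence | np.ndarray,
    tm_ids: np.ndarray | None,
    x_vocal: EmgFeatureSequence | np.ndarray | None,
    cfg: TrainConfig,
) -> LossBreakdown:
    """Evaluate the joint objective; keeps the graph for backprop."""
    Yf = Y.frames if isinstance(Y, MelSequence) else np.asarray(Y, dtype=np.float64)
    dv = d.d if isinstance(d, DurationSequence) else np.asarray(d, dtype=np.float64)
    if out.mel_post.shape != Yf.shape:
        raise ValueError(
            f"mel prediction {out.mel_post.shape} does not match target {Yf.shape}"
        )
    if out.durations_pred.shape[0] != dv.size:
        raise ValueError("duration prediction length mismatch")

    target = Tensor(Yf)
    mae_post = (out.mel_post - target).abs().mean()
    mae_pre = (out.mel_pre - target).abs().mean()
    mse_dur = (out.durations_pred - Tensor(dv.astype(np.float64))).pow(2.0).mean()
    total = mae_post + mae_pre + mse_dur

    ce = Tensor(0.0)
    if cfg.lambda_tm > 0 and out.toneme_logits is not None and tm_ids is not None:
        tm_ids = np.asarray(tm_ids, dtype=np.int64)
        if tm_ids.size != out.toneme_logits.shape[0]:
            raise ValueError("toneme label length mismatch")
        ce = out.toneme_logits.cross_entropy(tm_ids)
        total = total + cfg.lambda_tm * ce

    mse_recon = Tensor(0.0)
    if cfg.lambda_recons > 0 and out.emg_recon is not None and x_vocal is not None:
        xf = (
            x_vocal.frames
            if isinstance(x_vocal, EmgFeatureSequence)
            else np.asarray(x_vocal, dtype=np.float64)
        )
        if out.emg_recon.shape != xf.shape:
            raise ValueError("vocal-EMG reconstruction shape mismatch")
        mse_recon = (out.emg_recon - Tensor(xf)).pow(2.0).mean()
        total = total + cfg.lambda_recons * mse_recon

    return LossBreakdown(
        mae_post=mae_post.item(),
        mae_pre=mae_pre.item(),
        mse_duration=mse_dur.item(),
        ce_toneme=ce.item(),
        mse_recon=mse_recon.item(),
        total=total.item(),
        total_tensor=total,
    )


def noam_lr(step: int, d_model: int = 384, step_w: int = 4000) -> float:
    """Warmup-then-decay learning rate; peaks at step = step_w."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return d_model**-0.5 * min(step**-0.5, step * step_w**-1.5)


def duration_refresh_policy(epoch: int, cfg: TrainConfig) -> str:
    """Which duration source epoch ``epoch`` (1-based) trains against.

    Epochs 1..initial_plain_cost_epochs use the bootstrap durations from
    the plain EMG-distance DTW; every duration_refresh_period-th epoch
    recomputes durations with the refined (mel-augmented) cost; all other
    epochs reuse the cached durations.
    """
    if epoch <= cfg.initial_plain_cost_epochs:
        return "use_initial"
    if epoch % cfg.duration_refresh_period == 0:
        return "refresh_with_refined_cost"
    return "keep_cached"


# ---------------------------------------------------------------------------
# corpus preparation and the loop


@dataclass
class PreparedUtterance:
    """Featurized, normalized training sample on both timelines."""

    X: np.ndarray  # silent EMG features [N x 355], normalized
    x: np.ndarray  # vocal EMG features [M x 355], normalized
    Y: np.ndarray  # vocal mel [M x 80], normalized
    tm_ids: np.ndarray  # [M] toneme class ids
    durations: np.ndarray  # current GT durations [N], sum = M
    uid: str = ""


def _mean_std(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    stacked = np.concatenate(mats, axis=0)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd < 1e-8] = 1.0
    return mu, sd


def prepare_corpus(
    samples: list,
    inventory: dict[str, int],
    normalization: dict[str, np.ndarray] | None = None,
) -> tuple[list[PreparedUtterance], dict[str, np.ndarray]]:
    """Featurize utterances and z-score normalize features and mel targets.

    ``samples`` are synthetic or real utterances exposing silent/vocal EMG,
    audio and frame labels (see synthdata.UtteranceSample).  Normalization
    statistics are computed here when not supplied (training split) and
    reused otherwise (validation/test).
    """
    from .sigproc import extract_emg_features, extract_mel

    raw = []
    for s in samples:
        X = extract_emg_features(s.silent_emg).frames
        x = extract_emg_features(s.vocal_emg).frames
        Y = extract_mel(s.audio).frames
        M = min(x.shape[0], Y.shape[0], len(s.toneme_labels))
        x, Y = x[:M], Y[:M]
        tm_ids = np.array([inventory[l] for l in s.toneme_labels.labels[:M]])
        raw.append((s, X, x, Y, tm_ids))

    if normalization is None:
        emg_mu, emg_sd = _mean_std([r[1] for r in raw] + [r[2] for r in raw])
        mel_mu, mel_sd = _mean_std([r[3] for r in raw])
        normalization = {
            "emg_mean": emg_mu,
            "emg_std": emg_sd,
            "mel_mean": mel_mu,
            "mel_std": mel_sd,
        }
    prepped = []
    for s, X, x, Y, tm_ids in raw:
        Xn = (X - normalization["emg_mean"]) / normalization["emg_std"]
        xn = (x - normalization["emg_mean"]) / normalization["emg_std"]
        Yn = (Y - normalization["mel_mean"]) / normalization["mel_std"]
        align = dtw(Xn, xn)
        d = np.bincount(align.assignment - 1, minlength=Xn.shape[0])
        prepped.append(
            PreparedUtterance(
                X=Xn, x=xn, Y=Yn, tm_ids=tm_ids, durations=d,
                uid=getattr(s, "uid", ""),
            )
        )
    return prepped, normalization


def _refresh_durations(model: SSRNet, utt: PreparedUtterance, lambda_align: float) -> None:
    """Recompute GT durations with the refined, mel-augmented DTW cost."""
    y_pred = model.forward_unregulated(utt.X).frames
    extra = lambda_align * _mel_distance(y_pred, utt.Y)
    align = dtw(utt.X, utt.x, extra=extra)
    M = utt.x.shape[0]
    d = np.bincount(align.assignment - 1, minlength=utt.X.shape[0])
    assert int(d.sum()) == M
    utt.durations = d


def _mel_distance(yp: np.ndarray, yt: np.ndarray) -> np.ndarray:
    from .alignment import pairwise_distance

    return pairwise_distance(yp, yt)


def _utterance_loss(model: SSRNet, utt: PreparedUtterance, cfg: TrainConfig, training: bool) -> LossBreakdown:
    out = model.forward_train(utt.X, utt.durations, training=training)
    return ssrnet_loss(out, utt.Y, utt.durations, utt.tm_ids, utt.x, cfg)


def train(
    corpus: list[PreparedUtterance],
    model: SSRNet,
    cfg: TrainConfig,
    val_corpus: list[PreparedUtterance] | None = None,
    log_path: str | Path | None = None,
    scorer=None,
) -> tuple[SSRNet, list[dict]]:
    """Run the training loop; returns the model (best-validation weights).

    Checkpoint selection uses validation total loss by default; ``scorer``
    may be any callable (model, val_corpus) -> float where lower is better
    (e.g. an external ASR-based character error rate).
    """
    if not corpus:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters())
    initial_durations = [u.durations.copy() for u in corpus]
    log: list[dict] = []
    best_score = np.inf
    best_state: dict[str, np.ndarray] | None = None
    step = 0
    for epoch in range(1, cfg.max_epochs + 1):
        policy = duration_refresh_policy(epoch, cfg)
        if policy == "use_initial":
            for u, d0 in zip(corpus, initial_durations):
                u.durations = d0.copy()
        elif policy == "refresh_with_refined_cost":
            for u in corpus:
                _refresh_durations(model, u, cfg.lambda_align)
        order = rng.permutation(len(corpus))
        epoch_terms: list[LossBreakdown] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            for idx in batch:
                lb = _utterance_loss(model, corpus[idx], cfg, training=True)
                (lb.total_tensor / len(batch)).backward()
                epoch_terms.append(lb)
            step += 1
            opt.lr = cfg.lr_scale * noam_lr(step, cfg.d_model_schedule, cfg.step_w)
            opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
        model.is_trained = True
        entry = {
            "epoch": epoch,
            "policy": policy,
            "steps": step,
            "lr": opt.lr,
        }
        mean_terms = {
            k: float(np.mean([t.as_dict()[k] for t in epoch_terms]))
            for k in epoch_terms[0].as_dict()
        }
        entry.update({f"train_{k}": v for k, v in mean_terms.items()})
        if val_corpus:
            val_total = float(
                np.mean(
                    [
                        _utterance_loss(model, u, cfg, training=False).total
                        for u in val_corpus
                    ]
                )
            )
            entry["val_total"] = val_total
            score = scorer(model, val_corpus) if scorer is not None else val_total
        else:
            score = mean_terms["total"]
        entry["selection_score"] = float(score)
        log.append(entry)
        if score < best_score:
            best_score = score
            best_state = {k: p.data.copy() for k, p in model.params.items()}
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return model, log
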
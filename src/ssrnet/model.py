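"""The silent-speech reconstruction network (SSRNet).

A non-autoregressive sequence-to-sequence model mapping an N-frame silent
EMG feature sequence to an M-frame mel-spectrogram:

    encoder (linear+ReLU, positional encoding, feed-forward-transformer
    blocks)  ->  length regulator (repeat frame i by its duration d[i])
    ->  decoder (FFT blocks, linear to 80 mel bands, convolutional postnet
    residual).

Each feed-forward-transformer (FFT) block is multi-head self-attention
followed by a two-layer 1-D convolutional network, both with residual
connections and layer normalization.  A small convolutional duration
predictor estimates d from the encoder output so that inference can run
without ground-truth alignments.  Two training-only heads read the
regulated hidden states: a toneme classifier (frame-level onset / toned
nucleus / coda / sil labels) and a vocal-EMG reconstruction head; both
are discarded at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from .alignment import DurationSequence
from .containers import EMG_FEATURE_DIM, HOP_S, MEL_DIM, EmgFeatureSequence, MelSequence

__all__ = ["ModelConfig", "ModelOutput", "SSRNet"]


@dataclass
class ModelConfig:
    """Hyper-parameters of the network (defaults follow the full model)."""

    d_model: int = 384
    n_heads: int = 4
    encoder_layers: int = 6
    decoder_layers: int = 6
    conv_hidden: int = 1536
    conv_kernel: int = 3
    postnet_layers: int = 5
    postnet_channels: int = 256
    postnet_kernel: int = 5
    duration_layers: int = 2
    duration_channels: int = 384
    duration_kernel: int = 3
    dropout: float = 0.1
    postnet_dropout: float = 0.5
    input_dim: int = EMG_FEATURE_DIM
    mel_dim: int = MEL_DIM
    toneme_head_position: str = "before_decoder"
    inventory_size: int | None = None
    stop_duration_gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.toneme_head_position not in ("before_decoder", "after_decoder"):
            raise ValueError("toneme_head_position must be before_decoder or after_decoder")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """A CPU-friendly configuration for small synthetic corpora."""
        base = dict(
            d_model=32,
            n_heads=2,
            encoder_layers=2,
            decoder_layers=2,
            conv_hidden=64,
            postnet_channels=32,
            duration_channels=32,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class ModelOutput:
    """All tensors a training forward pass produces."""

    mel_pre: Tensor
    mel_post: Tensor
    durations_pred: Tensor
    toneme_logits: Tensor | None
    emg_recon: Tensor | None
    hidden_regulated: Tensor


def sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional encoding matrix [length x d_model]."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.zeros((length, d_model))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class SSRNet:
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        self.is_trained = False
        self.normalization: dict[str, np.ndarray] = {}
        self.inventory: list[str] | None = None
        self._build()

    # ---- parameter construction -----------------------------------------

    def _param(self, name: str, shape, fan_in: int | None = None) -> Tensor:
        if fan_in is None:
            data = np.zeros(shape)
        else:
            fan_out = shape[-1] if len(shape) > 1 else shape[0]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            data = self._rng.uniform(-bound, bound, size=shape)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _linear(self, name: str, din: int, dout: int) -> None:
        self._param(f"{name}.W", (din, dout), fan_in=din)
        self._param(f"{name}.b", (dout,))

    def _conv(self, name: str, k: int, cin: int, cout: int) -> None:
        self._param(f"{name}.W", (k, cin, cout), fan_in=k * cin)
        self._param(f"{name}.b", (cout,))

    def _ln(self, name: str, d: int) -> None:
        self.params[f"{name}.g"] = Tensor(np.ones(d), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(d), requires_grad=True)

    def _fft_stack(self, prefix: str, n_layers: int) -> None:
        c = self.cfg
        for l in range(n_layers):
            p = f"{prefix}.{l}"
            for h in ("q", "k", "v", "o"):
                self._linear(f"{p}.attn.{h}", c.d_model, c.d_model)
            self._ln(f"{p}.ln1", c.d_model)
            self._conv(f"{p}.conv1", c.conv_kernel, c.d_model, c.conv_hidden)
            self._conv(f"{p}.conv2", c.conv_kernel, c.conv_hidden, c.d_model)
            self._ln(f"{p}.ln2", c.d_model)

    def _build(self) -> None:
        c = self.cfg
        self._linear("in_proj", c.input_dim, c.d_model)
        self.params["pe_scale"] = Tensor(np.ones(1), requires_grad=True)
        self._fft_stack("enc", c.encoder_layers)
        self._fft_stack("dec", c.decoder_layers)
        # duration predictor: conv stack + linear head
        cin = c.d_model
        for l in range(c.duration_layers):
            self._conv(f"dur.conv{l}", c.duration_kernel, cin, c.duration_channels)
            self._ln(f"dur.ln{l}", c.duration_channels)
            cin = c.duration_channels
        self._linear("dur.out", cin, 1)
        self._linear("dec_out", c.d_model, c.mel_dim)
        # postnet
        ch = [c.mel_dim] + [c.postnet_channels] * (c.postnet_layers - 1) + [c.mel_dim]
        for l in range(c.postnet_layers):
            self._conv(f"post.conv{l}", c.postnet_kernel, ch[l], ch[l + 1])
        if c.inventory_size is not None:
            self._linear("toneme_head", c.d_model, c.inventory_size)
        self._linear("recon_head", c.d_model, c.input_dim)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # ---- building blocks -------------------------------------------------

    def _apply_linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _attention(self, prefix: str, x: Tensor, mask: np.ndarray | None) -> Tensor:
        c = self.cfg
        L = x.shape[0]
        dh = c.d_model // c.n_heads
        q = self._apply_linear(f"{prefix}.q", x)
        k = self._apply_linear(f"{prefix}.k", x)
        v = self._apply_linear(f"{prefix}.v", x)
        # [L, d] -> [heads, L, dh]
        q = q.reshape(L, c.n_heads, dh).transpose(1, 0, 2)
        k = k.reshape(L, c.n_heads, dh).transpose(1, 0, 2)
        v = v.reshape(L, c.n_heads, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        if mask is not None:
            bias = np.where(np.asarray(mask, dtype=bool), 0.0, -1e9)[None, None, :]
            scores = scores + Tensor(np.broadcast_to(bias, (c.n_heads, L, L)).copy())
        attn = scores.softmax_last()
        ctx = (attn @ v).transpose(1, 0, 2).reshape(L, c.d_model)
        return self._apply_linear(f"{prefix}.o", ctx)

    def _fft_block(
        self,
        prefix: str,
        x: Tensor,
        mask: np.ndarray | None,
        training: bool,
    ) -> Tensor:
        c = self.cfg
        if mask is not None:
            x = x.mask_rows(mask)
        a = self._attention(f"{prefix}.attn", x, mask)
        a = a.dropout(c.dropout, self._dropout_rng, training)
        x = (x + a).layer_norm(self.params[f"{prefix}.ln1.g"], self.params[f"{prefix}.ln1.b"])
        if mask is not None:
            x = x.mask_rows(mask)
        h = x.conv1d(self.params[f"{prefix}.conv1.W"], self.params[f"{prefix}.conv1.b"]).relu()
        h = h.conv1d(self.params[f"{prefix}.conv2.W"], self.params[f"{prefix}.conv2.b"])
        h = h.dropout(c.dropout, self._dropout_rng, training)
        x = (x + h).layer_norm(self.params[f"{prefix}.ln2.g"], self.params[f"{prefix}.ln2.b"])
        if mask is not None:
            x = x.mask_rows(mask)
        return x

    def fft_block(
        self, h: np.ndarray | Tensor, mask: np.ndarray | None = None, layer: str = "enc.0"
    ) -> Tensor:
        """Apply one named FFT block (exposed for structural testing)."""
        x = h if isinstance(h, Tensor) else Tensor(h)
        if mask is not None and len(mask) != x.shape[0]:
            raise ValueError("mask length must match sequence length")
        return self._fft_block(layer, x, mask, training=False)

    # ---- model stages ----------------------------------------------------

    @staticmethod
    def _frames(X) -> np.ndarray:
        if isinstance(X, (EmgFeatureSequence, MelSequence)):
            return X.frames
        return np.asarray(X, dtype=np.float64)

    def encode(self, X, training: bool = False, mask: np.ndarray | None = None) -> Tensor:
        frames = self._frames(X)
        if frames.ndim != 2 or frames.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"expected [N x {self.cfg.input_dim}] input, got {frames.shape}"
            )
        if frames.shape[0] == 0:
            raise ValueError("empty input sequence")
        x = self._apply_linear("in_proj", Tensor(frames)).relu()
        pe = sinusoidal_positions(frames.shape[0], self.cfg.d_model)
        x = x + self.params["pe_scale"] * Tensor(pe)
        for l in range(self.cfg.encoder_layers):
            x = self._fft_block(f"enc.{l}", x, mask, training)
        return x

    def predict_durations(self, h: Tensor, training: bool = False) -> Tensor:
        """Non-negative real-valued duration estimate per encoder frame."""
        c = self.cfg
        x = h
        if c.stop_duration_gradient:
            x = Tensor(h.data)
        for l in range(c.duration_layers):
            x = x.conv1d(self.params[f"dur.conv{l}.W"], self.params[f"dur.conv{l}.b"]).relu()
            x = x.layer_norm(self.params[f"dur.ln{l}.g"], self.params[f"dur.ln{l}.b"])
            x = x.dropout(c.dropout, self._dropout_rng, training)
        d = self._apply_linear("dur.out", x).relu()
        return d.reshape(-1)

    def decode(self, h_reg: Tensor, training: bool = False) -> tuple[Tensor, Tensor]:
        """FFT decoder + linear mel projection, then postnet residual."""
        c = self.cfg
        x = h_reg
        for l in range(c.decoder_layers):
            x = self._fft_block(f"dec.{l}", x, None, training)
        mel_pre = self._apply_linear("dec_out", x)
        r = mel_pre
        for l in range(c.postnet_layers):
            r = r.conv1d(self.params[f"post.conv{l}.W"], self.params[f"post.conv{l}.b"])
            if l < c.postnet_layers - 1:
                r = r.tanh().dropout(c.postnet_dropout, self._dropout_rng, training)
        mel_post = mel_pre + r
        self._last_decoder_hidden = x
        return mel_pre, mel_post

    def joint_heads(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """Toneme logits [M x K] and vocal-EMG reconstruction [M x 355]."""
        if self.cfg.inventory_size is None:
            raise ValueError("inventory_size is unset; register a toneme inventory first")
        return self._apply_linear("toneme_head", h), self._apply_linear("recon_head", h)

    def forward_train(self, X, d: DurationSequence | np.ndarray, training: bool = True) -> ModelOutput:
        """Full training-mode pass using ground-truth durations."""
        counts = d.d if isinstance(d, DurationSequence) else np.asarray(d, dtype=np.int64)
        frames = self._frames(X)
        if counts.size != frames.shape[0]:
            raise ValueError("duration length must equal the number of input frames")
        h = self.encode(X, training=training)
        d_hat = self.predict_durations(h, training=training)
        h_reg = h.repeat_rows(counts)
        toneme_logits = None
        emg_recon = None
        if self.cfg.toneme_head_position == "before_decoder":
            if self.cfg.inventory_size is not None:
                toneme_logits, emg_recon = self.joint_heads(h_reg)
        mel_pre, mel_post = self.decode(h_reg, training=training)
        if self.cfg.toneme_head_position == "after_decoder":
            if self.cfg.inventory_size is not None:
                toneme_logits, emg_recon = self.joint_heads(self._last_decoder_hidden)
        return ModelOutput(
            mel_pre=mel_pre,
            mel_post=mel_post,
            durations_pred=d_hat,
            toneme_logits=toneme_logits,
            emg_recon=emg_recon,
            hidden_regulated=h_reg,
        )

    def infer_durations(self, X) -> np.ndarray:
        """Rounded non-negative durations with total forced >= 1."""
        h = self.encode(X, training=False)
        d_hat = self.predict_durations(h, training=False).data
        # round half away from zero on a non-negative vector
        d_int = np.floor(d_hat + 0.5).astype(np.int64)
        if d_int.sum() < 1:
            d_int[int(np.argmax(d_hat))] = 1
        return d_int

    def forward_infer(self, X) -> MelSequence:
        """Inference: predicted durations, joint heads discarded."""
        if not self.is_trained:
            raise RuntimeError(
                "model has no trained parameters; train it or load a checkpoint"
            )
        h = self.encode(X, training=False)
        d_hat = self.predict_durations(h, training=False).data
        d_int = np.floor(d_hat + 0.5).astype(np.int64)
        if d_int.sum() < 1:
            d_int[int(np.argmax(d_hat))] = 1
        h_reg = h.repeat_rows(d_int)
        _, mel_post = self.decode(h_reg, training=False)
        return MelSequence(mel_post.data, hop_s=HOP_S)

    def forward_unregulated(self, X) -> MelSequence:
        """N-length mel prediction bypassing the length regulator.

        Equivalent to a forward pass with all durations equal to one; used
        by the refined alignment cost during training.
        """
        h = self.encode(X, training=False)
        _, mel_post = self.decode(h, training=False)
        return MelSequence(mel_post.data, hop_s=HOP_S)

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.cfg),
            "is_trained": self.is_trained,
            "inventory": self.inventory,
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        for k, v in self.normalization.items():
            arrays[f"norm____{k}"] = np.asarray(v)
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SSRNet":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]))
            for k in z.files:
                if k == "__meta__":
                    continue
                if k.startswith("norm____"):
                    model.normalization[k[len("norm____"):]] = z[k]
                else:
                    model.params[k.replace("__", ".")].data = z[k].astype(np.float64)
        model.is_trained = bool(meta["is_trained"])
        model.inventory = meta["inventory"]
        return model
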
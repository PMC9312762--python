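"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor calculus for a feed-forward transformer: broadcasting
elementwise arithmetic, (batched) matmul, softmax, layer normalization,
1-D convolution over a sequence, row repetition (the length regulator),
dropout and fused softmax cross-entropy.  Graphs are built eagerly;
``Tensor.backward()`` runs a topological sweep accumulating gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- graph machinery -------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def matmul(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.data.shape)
        )
        return out

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def softmax_last(self):
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bw(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gain.data + bias.data, parents=(self, gain, bias))
        D = self.data.shape[-1]

        def bw(g):
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.data.shape))
            if self.requires_grad:
                gx = g * gain.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                    gx * xhat
                ).mean(axis=-1, keepdims=True)
                self._accum(term * inv)

        out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)
        out = Tensor(self.data * keep, parents=(self,))
        out._backward = lambda g: self._accum(g * keep)
        return out

    # ---- sequence ops ----------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """'Same' 1-D convolution over axis 0.

        self: [L x Cin]; weight: [k x Cin x Cout]; bias: [Cout] -> [L x Cout].
        """
        x = self.data
        W = weight.data
        k = W.shape[0]
        left = (k - 1) // 2
        right = k - 1 - left
        xp = np.pad(x, ((left, right), (0, 0)))
        L = x.shape[0]
        y = np.zeros((L, W.shape[2]))
        for t in range(k):
            y += xp[t : t + L] @ W[t]
        y += bias.data
        out = Tensor(y, parents=(self, weight, bias))

        def bw(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=0))
            if weight.requires_grad:
                gw = np.empty_like(W)
                for t in range(k):
                    gw[t] = xp[t : t + L].T @ g
                weight._accum(gw)
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for t in range(k):
                    gxp[t : t + L] += g @ W[t].T
                self._accum(gxp[left : left + L])

        out._backward = bw
        return out

    def repeat_rows(self, counts: np.ndarray):
        """Length regulation: repeat row i counts[i] times along axis 0."""
        counts = np.asarray(counts, dtype=np.int64)
        out_data = np.repeat(self.data, counts, axis=0)
        out = Tensor(out_data, parents=(self,))
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

        def bw(g):
            gg = np.zeros_like(self.data)
            nz = counts > 0
            summed = np.add.reduceat(g, starts[nz], axis=0) if nz.any() else None
            if summed is not None:
                gg[nz] = summed
            self._accum(gg)

        out._backward = bw
        return out

    def mask_rows(self, mask: np.ndarray):
        """Zero rows where mask is False (mask: boolean [L])."""
        m = np.asarray(mask, dtype=bool).reshape(-1, *([1] * (self.data.ndim - 1)))
        out = Tensor(self.data * m, parents=(self,))
        out._backward = lambda g: self._accum(g * m)
        return out

    def cross_entropy(self, labels: np.ndarray, weights: np.ndarray | None = None):
        """Mean softmax cross-entropy of logits [L x K] against int labels."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        L = self.data.shape[0]
        w = np.ones(L) if weights is None else np.asarray(weights, dtype=np.float64)
        denom = max(w.sum(), 1e-12)
        nll = -(w * logp[np.arange(L), labels]).sum() / denom
        out = Tensor(nll, parents=(self,))

        def bw(g):
            p = np.exp(logp)
            p[np.arange(L), labels] -= 1.0
            self._accum(g * p * (w / denom)[:, None])

        out._backward = bw
        return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.98), eps=1e-9):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad**2).sum())
        norm = total**0.5
        if norm > max_norm and norm > 0:
            scale = max_norm / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
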
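"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the trainable parts of the pipeline need:
dense layers, layer normalization, multi-head self-attention, and the
focal / InfoNCE objectives. Gradients are accumulated by a topological
backward sweep over a dynamically recorded graph. Correctness is enforced
by finite-difference checks in the test suite rather than by breadth of
features.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["Tensor", "concat", "Linear", "MLP", "LayerNorm", "MultiHeadSelfAttention",
           "TransformerBlock", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = _as_tensor(other)
        out = Tensor(self.data + o.data, parents=(self, o))
        out._backward = lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        o = _as_tensor(other)
        out = Tensor(self.data * o.data, parents=(self, o))
        out._backward = lambda g: (_unbroadcast(g * o.data, self.shape),
                                   _unbroadcast(g * self.data, o.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        out = Tensor(self.data / o.data, parents=(self, o))
        out._backward = lambda g: (_unbroadcast(g / o.data, self.shape),
                                   _unbroadcast(-g * self.data / o.data ** 2, o.shape))
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        o = _as_tensor(other)
        out = Tensor(self.data @ o.data, parents=(self, o))
        out._backward = lambda g: (g @ o.data.T, self.data.T @ g)
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1 - y ** 2),)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1 - y),)
        return out

    # -- reductions and shape ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        out._backward = back
        return out

    # -- composed helpers ---------------------------------------------------

    def l2_normalize_rows(self, eps: float = 1e-12) -> "Tensor":
        # eps inside the root keeps the gradient finite for zero-norm rows
        norms = ((self * self).sum(axis=1, keepdims=True) + eps) ** 0.5
        return self / norms

    def softmax_rows(self) -> "Tensor":
        shift = Tensor(self.data.max(axis=-1, keepdims=True))  # constant, no grad
        e = (self - shift).exp()
        return e / e.sum(axis=-1, keepdims=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def back(g):
        splits = np.cumsum(sizes)[:-1]
        return tuple(np.split(g, splits, axis=axis))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.array(a, dtype=float)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def checksum(self) -> str:
        """Byte-exact parameter digest used by the frozen-backbone audits."""
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP(Module):
    """Fully connected stack with ReLU between layers and a linear final layer."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dims = list(dims)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


class MultiHeadSelfAttention(Module):
    """Self-attention over a token sequence; no positional encoding.

    Patches in a bag are an unordered set, so outputs are permutation
    equivariant and the summary token is permutation invariant.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:  # x: (n_tokens, dim)
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        outs = []
        for h in range(self.n_heads):
            sl = slice(h * self.dh, (h + 1) * self.dh)
            qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
            scores = (qh @ kh.T) * (1.0 / np.sqrt(self.dh))
            outs.append(scores.softmax_rows() @ vh)
        return self.wo(concat(outs, axis=1))

    def parameters(self):
        return [p for l in (self.wq, self.wk, self.wv, self.wo) for p in l.parameters()]


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())

    def parameters(self):
        return (self.attn.parameters() + self.ln1.parameters() + self.ln2.parameters()
                + self.ff1.parameters() + self.ff2.parameters())


class Adam:
    """Adam with decoupled weight decay; skips parameters with no gradient.

    Decay is applied directly to the weights (AdamW style) rather than
    through the gradient, where Adam's per-parameter scaling would largely
    neutralize it.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.weight_decay * p.data)
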
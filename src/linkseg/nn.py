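"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the heterogeneous attention network needs:
broadcast arithmetic, matrix products, row gathers and segment reductions
(scatter-add and a numerically stable fused segment softmax), the usual
elementwise nonlinearities, and an Adam optimizer. Everything is plain
float64 numpy, so training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = lambda: None
        self._prev = _prev
        self._grad_owned = False

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is adopted by reference; a second contribution
        # forces a copy so aliased upstream gradients are never mutated
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # ------------------------------------------------------------------ ops
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / max(self.data.size, 1))

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        # stable: max(x, 0) + log1p(exp(-|x|))
        out = Tensor(np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data))), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / (1.0 + np.exp(-self.data)))

        out._backward = backward
        return out

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Row selection ``self[idx]`` with scatter-add backward."""
        out = Tensor(self.data[idx], _prev=(self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = backward
        return out

    def segment_sum(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` buckets given per-row segment ids."""
        shape = (n_segments,) + self.data.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, seg, self.data)
        out = Tensor(acc, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad[seg])

        out._backward = backward
        return out

    def segment_softmax(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Softmax normalized within each segment (stable, fused backward).

        For per-edge logits with destination-node segment ids this yields
        attention weights that are nonnegative and sum to one over each
        destination's incoming edges.
        """
        shape = (n_segments,) + self.data.shape[1:]
        m = np.full(shape, -np.inf)
        np.maximum.at(m, seg, self.data)
        m = np.where(np.isfinite(m), m, 0.0)
        ex = np.exp(self.data - m[seg])
        denom = np.zeros(shape)
        np.add.at(denom, seg, ex)
        alpha = ex / denom[seg]
        out = Tensor(alpha, _prev=(self,))

        def backward():
            if self.requires_grad:
                weighted = alpha * out.grad
                acc = np.zeros(shape)
                np.add.at(acc, seg, weighted)
                self._accumulate(weighted - alpha * acc[seg])

        out._backward = backward
        return out

    # ------------------------------------------------------------- backward
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        for node in reversed(topo):
            node._backward()
            # free the graph as we go: intermediate grads are never read
            # again, and dropping closures breaks reference cycles so large
            # activations are reclaimed by refcount, not the gc
            if node._prev:
                node.grad = None
                node._backward = lambda: None
                node._prev = ()

    def detach(self) -> np.ndarray:
        return self.data

    def release(self) -> None:
        """Drop the autodiff graph below this tensor (for eval-mode passes
        whose backward will never run)."""
        stack = [self]
        while stack:
            node = stack.pop()
            if node._prev:
                stack.extend(node._prev)
                node._prev = ()
                node._backward = lambda: None


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def bce_with_logits(logits: Tensor, labels: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Weighted mean binary cross-entropy on raw scores.

    Per-sample loss is softplus(x) - x*z; positives are weighted by
    ``pos_weight`` (and the mean renormalized), which undoes the intercept
    bias introduced by subsampling negatives at a fixed ratio.
    """
    labels = np.asarray(labels, dtype=np.float64)
    w = np.where(labels > 0, pos_weight, 1.0)
    w = w / w.mean()
    return ((logits.softplus() - logits * labels) * (w / labels.size)).sum()


class Adam:
    """Adam with bias correction over a flat parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.lr_overrides = lr_overrides or {}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            lr = self.lr_overrides.get(k, self.lr)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
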
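"""Parameterised building blocks and optimizers for the desk-scale models."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .ops3d import conv3d

__all__ = [
    "Module", "Conv3d", "GroupNorm", "BatchNorm", "Linear", "LSTMCell", "Adam", "AdamW",
]


class Module:
    """Lightweight parameter container with flat (name -> array) state."""

    def _walk(self, prefix: str = ""):
        """Yield (name, Tensor) for every parameter and buffer, recursing
        through nested Modules, lists and tuples."""

        def visit(key, value):
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, Module):
                yield from value._walk(key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from visit(f"{key}.{i}", item)

        for name, value in vars(self).items():
            yield from visit(f"{prefix}{name}", value)

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self._walk() if t.requires_grad]

    def modules(self):
        yield self
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Module):
                    yield from item.modules()

    def set_training(self, flag: bool) -> None:
        for module in self.modules():
            if hasattr(module, "training"):
                module.training = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self._walk()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self._walk())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for key, tensor in own.items():
            tensor.data = np.asarray(state[key], dtype=tensor.data.dtype).reshape(
                tensor.data.shape
            )


def _param(arr: np.ndarray) -> Tensor:
    t = Tensor(arr.astype(np.float32))
    t.requires_grad = True
    return t


class Conv3d(Module):
    """3x3x3 (or 1x1x1) stride-1 same-padding convolution, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k**3
        self.weight = _param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k)))
        self.bias = _param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalization over (channel-group, spatial) statistics.

    Batch-size independent and free of running state, so training is
    deterministic and inference needs no mode switch; the stand-in for the
    per-conv batch normalization of the reference architectures, which is
    ill-behaved at batch size 2.
    """

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.eps = eps
        self.gain = _param(np.ones(channels))
        self.shift = _param(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        # fused forward/backward: one composite op instead of ~15 temporaries
        n, c = x.shape[0], x.shape[1]
        spatial = tuple(x.shape[2:])
        g, eps = self.groups, self.eps
        gain, shift = self.gain, self.shift
        xd = x.data.reshape(n, g, -1)
        mu = xd.mean(axis=2, keepdims=True)
        xc = xd - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xc * inv).reshape((n, c) + spatial)
        bshape = (1, c) + (1,) * len(spatial)
        out = xhat * gain.data.reshape(bshape) + shift.data.reshape(bshape)

        def backward(grad):
            dgain = (grad * xhat).sum(axis=(0,) + tuple(range(2, 2 + len(spatial))))
            dshift = grad.sum(axis=(0,) + tuple(range(2, 2 + len(spatial))))
            gx = (grad * gain.data.reshape(bshape)).reshape(n, g, -1)
            xh = xhat.reshape(n, g, -1)
            m1 = gx.mean(axis=2, keepdims=True)
            m2 = (gx * xh).mean(axis=2, keepdims=True)
            dx = (gx - m1 - xh * m2) * inv
            return (
                dx.reshape(x.shape),
                dgain.reshape(gain.shape),
                dshift.reshape(shift.shape),
            )

        return Tensor._make(out, (x, gain, shift), backward)


class BatchNorm(Module):
    """Per-channel batch normalization over (batch, spatial) statistics,
    with running estimates for inference.

    Unlike group/instance variants this preserves per-sample global
    intensity offsets — which carry real signal here (a calcified or
    ground-glass nodule shifts the whole patch mean) — at the cost of
    needing a train/eval mode switch.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.training = True
        self.gain = _param(np.ones(channels))
        self.shift = _param(np.zeros(channels))
        self.running_mean = Tensor(np.zeros(channels, dtype=np.float32))
        self.running_var = Tensor(np.ones(channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        red = (0,) + tuple(range(2, x.ndim))
        bshape = (1, c) + (1,) * (x.ndim - 2)
        gain, shift = self.gain, self.shift
        if not self.training:
            inv = 1.0 / np.sqrt(self.running_var.data + self.eps)
            scale = Tensor((gain.data * inv).reshape(bshape))
            offset = Tensor(
                (shift.data - gain.data * self.running_mean.data * inv).reshape(bshape)
            )
            return x * scale + offset

        mu = x.data.mean(axis=red)
        xc = x.data - mu.reshape(bshape)
        var = (xc * xc).mean(axis=red)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        xhat = xc * inv.reshape(bshape)
        m = self.momentum
        self.running_mean.data = (1 - m) * self.running_mean.data + m * mu
        self.running_var.data = (1 - m) * self.running_var.data + m * var
        out = xhat * gain.data.reshape(bshape) + shift.data.reshape(bshape)

        def backward(grad):
            dgain = (grad * xhat).sum(axis=red)
            dshift = grad.sum(axis=red)
            g = grad * gain.data.reshape(bshape)
            m1 = g.mean(axis=red).reshape(bshape)
            m2 = (g * xhat).mean(axis=red).reshape(bshape)
            dx = (g - m1 - xhat * m2) * inv.reshape(bshape)
            return dx, dgain.reshape(gain.shape), dshift.reshape(shift.shape)

        return Tensor._make(out, (x, gain, shift), backward)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = _param(rng.normal(0.0, np.sqrt(1.0 / nin), (nin, nout)))
        self.bias = _param(np.zeros(nout))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTMCell(Module):
    """Single LSTM cell; gate order (input, forget, cell, output).

    Forget-gate bias initialised to 1, the usual trick to ease gradient flow
    early in training.
    """

    def __init__(self, nin: int, nhidden: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / nhidden)
        self.w_ih = _param(rng.uniform(-scale, scale, (nin, 4 * nhidden)))
        self.w_hh = _param(rng.uniform(-scale, scale, (nhidden, 4 * nhidden)))
        bias = np.zeros(4 * nhidden)
        bias[nhidden : 2 * nhidden] = 1.0
        self.bias = _param(bias)
        self.nhidden = nhidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.nhidden
        gates = x @ self.w_ih + h @ self.w_hh + self.bias
        i = gates[:, 0:nh].sigmoid()
        f = gates[:, nh : 2 * nh].sigmoid()
        g = gates[:, 2 * nh : 3 * nh].tanh()
        o = gates[:, 3 * nh : 4 * nh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class Adam:
    """Adam with the standard bias correction; lr may be changed between steps."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _update(self, p: Tensor, i: int) -> np.ndarray:
        g = p.grad
        if self.weight_decay and not self._decoupled:
            g = g + self.weight_decay * p.data
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        mhat = self.m[i] / (1 - self.b1**self.t)
        vhat = self.v[i] / (1 - self.b2**self.t)
        return mhat / (np.sqrt(vhat) + self.eps)

    _decoupled = False

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            update = self._update(p, i)
            if self._decoupled and self.weight_decay:
                p.data = p.data - self.lr * (update + self.weight_decay * p.data)
            else:
                p.data = p.data - self.lr * update


class AdamW(Adam):
    """Adam with decoupled weight decay (default 1e-2)."""

    _decoupled = True

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        super().__init__(params, lr=lr, betas=betas, eps=eps, weight_decay=weight_decay)
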
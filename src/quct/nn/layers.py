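"""Layer/module abstractions over the autodiff primitives.

Modules own :class:`Parameter` leaves and are traversed recursively for
optimization, counting and (de)serialization.  Convolution weights are
initialized with Kaiming-normal draws (fan-in mode) and zero biases; pass
``rng=None`` to allocate zero weights, which is cheap and sufficient for
architecture accounting.
"""

from __future__ import annotations

import numpy as np

from . import convops
from .tensor import Tensor, matmul, selu, sigmoid


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def kaiming_normal(rng, shape, fan_in):
    if rng is None:
        return np.zeros(shape, dtype=np.float32)
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        """Unique parameter leaves; shared submodules are yielded once."""
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise ValueError(
                f"checkpoint mismatch: missing={missing}, unexpected={unexpected}")
        bad = [n for n in own if own[n].data.shape != state[n].shape]
        if bad:
            raise ValueError(f"checkpoint shape mismatch in layers: {bad}")
        for name, p in own.items():
            p.data = state[name].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, dilation=1, padding="same",
                 depthwise=False, rng=None):
        kh, kw = convops._pair(kernel)
        self.stride, self.dilation, self.padding = stride, dilation, padding
        self.depthwise = depthwise
        if depthwise:
            if c_in != c_out:
                raise ValueError("depthwise conv requires c_in == c_out")
            self.w = Parameter(kaiming_normal(rng, (c_out, 1, kh, kw), kh * kw))
        else:
            self.w = Parameter(kaiming_normal(rng, (c_out, c_in, kh, kw),
                                              c_in * kh * kw))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x):
        return convops.conv2d(x, self.w, self.b, self.stride, self.dilation,
                              self.padding, self.depthwise)

    def out_shape(self, in_hw):
        return convops.conv_out_shape(in_hw, self.w.shape[-2:], self.stride,
                                      self.dilation, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel, stride, rng=None):
        kh, kw = convops._pair(kernel)
        self.stride = stride
        self.w = Parameter(kaiming_normal(rng, (c_in, c_out, kh, kw),
                                          c_in * kh * kw))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x):
        return convops.conv_transpose2d(x, self.w, self.b, self.stride)

    def out_shape(self, in_hw):
        return convops.conv_transpose_out_shape(in_hw, self.w.shape[-2:], self.stride)


class Dense(Module):
    def __init__(self, n_in, n_out, rng=None):
        self.w = Parameter(kaiming_normal(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out, dtype=np.float32))

    def forward(self, x):
        return matmul(x, self.w) + self.b


class LayerNorm(Module):
    """Channel-wise layer normalization (per spatial position)."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x):
        return convops.layer_norm(x, self.gamma, self.beta, self.eps)


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration.

    Global average pooling condenses each channel to one value; a two-layer
    gated bottleneck (SELU then sigmoid) produces per-channel scales in
    (0, 1) that multiply the input.
    """

    def __init__(self, channels, hidden, rng=None):
        if hidden < 1 or hidden > channels:
            raise ValueError(f"SE hidden width {hidden} outside [1, {channels}]")
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.channels = channels

    def forward(self, x):
        squeezed = x.mean(axis=(2, 3))              # (N, C)
        scale = sigmoid(self.fc2(selu(self.fc1(squeezed))))
        return x * scale.reshape(x.shape[0], self.channels, 1, 1)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
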
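"""Small module system (layers, parameters, state dicts) over the autodiff core.

Conventions follow the mainstream deep-learning toolkits: NCHW layout,
He-normal weight initialization for convolutions, unit/zero init for
normalization affine parameters, and a ``train()``/``eval()`` mode switch
that controls whether batch statistics or running statistics are used.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor. ``decay`` marks it as subject to weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    """Base class with recursive parameter/submodule discovery."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for val in vars(self).items():
            pass
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.buffers(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{prefix}{name}.{i}.")

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data[...] = state[f"param.{k}"]
        for k, v in self.buffers():
            v[...] = state[f"buffer.{k}"]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """2D convolution, He-normal init; bias off when a BatchNorm follows."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)), decay=True
        )
        self.bias = Parameter(np.zeros(out_ch), decay=False) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)

    __call__ = forward


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return x.batchnorm2d(self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             momentum=self.momentum, eps=self.eps)

    __call__ = forward


_ACTIVATIONS = {
    "relu": Tensor.relu,
    "hardswish": Tensor.hardswish,
    "sigmoid": Tensor.sigmoid,
    "identity": lambda t: t,
}


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the workhorse composite.

    ``order="act_first"`` applies conv -> activation -> BatchNorm instead,
    matching the literal reading of the dense-chain non-linearity.
    """

    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, act="relu",
                 order: str = "bn_first"):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride, bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.act = act
        self.order = order

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        f = _ACTIVATIONS[self.act]
        if self.order == "act_first":
            return self.bn(f(y))
        return f(self.bn(y))

    __call__ = forward
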
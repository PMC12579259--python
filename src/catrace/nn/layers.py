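"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Minimal parameter container with recursive naming and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for mname, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + mname + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Conv3d(Module):
    """Same-padded 3D convolution layer with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (cin * k ** 3))
        self.stride = stride
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvBlock(Module):
    """Conv3d followed by ReLU."""

    def __init__(self, cin, cout, k, rng, stride=1):
        super().__init__()
        self.conv = Conv3d(cin, cout, k, rng, stride=stride)

    def __call__(self, x: Tensor) -> Tensor:
        return T.relu(self.conv(x))


class ChannelGate(Module):
    """Squeeze-style channel attention: GAP -> 1x1 convs -> sigmoid -> scale."""

    def __init__(self, channels: int, reduction: int, rng):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv3d(channels, hidden, 1, rng)
        self.fc2 = Conv3d(hidden, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        s = T.global_avg_pool(x)
        s = T.relu(self.fc1(s))
        s = T.sigmoid(self.fc2(s))
        return T.mul(x, s)


class SpatialGate(Module):
    """Local attention: 3x3x3 conv to one channel -> sigmoid -> scale."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv = Conv3d(channels, 1, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return T.mul(x, T.sigmoid(self.conv(x)))
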
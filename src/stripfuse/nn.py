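"""Neural-network building blocks: modules, layers, and the two backbone units.

Two kinds of surface live here.

* Pure-numpy reference primitives (:func:`conv2d_valid`, :func:`pool`): the
  textbook valid cross-correlation y[m,n] = sum_{p,q} f[m+p-1, n+q-1] k[p,q]
  and windowed average/max pooling.  They carry no gradients and exist as the
  ground-truth definitions the differentiable layers are tested against.

* Differentiable modules built on :mod:`stripfuse.autodiff`: ``Conv2d``,
  ``Conv1d``, ``BatchNorm2d``/``BatchNorm1d``, ``Linear``, ``Dropout``, and
  the two backbone units — ``SpatialBlock`` (3x3 conv -> batch norm -> ReLU
  -> optional 2x2 pool, VGG style) and ``ResidualBlock`` (conv -> BN -> ReLU
  -> conv -> ReLU, plus an identity or 1x1-projection shortcut added to the
  branch output; no post-addition ReLU and no batch norm after the second
  convolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    avg_pool2x2,
    batch_norm,
    conv2d,
    dropout,
    max_pool2x2,
)

__all__ = [
    "conv2d_valid",
    "PoolSpec",
    "pool",
    "Module",
    "Conv2d",
    "Conv1d",
    "BatchNorm2d",
    "BatchNorm1d",
    "Linear",
    "Dropout",
    "ReLU",
    "SpatialBlockConfig",
    "SpatialBlock",
    "ResidualBlockConfig",
    "ResidualBlock",
]


# ---------------------------------------------------------------------------
# reference primitives (pure numpy, no gradients)
# ---------------------------------------------------------------------------


def conv2d_valid(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Valid 2-D cross-correlation of a single-channel grid with a kernel.

    Output size is (M - r + 1) x (N - s + 1) for an M x N input and an
    r x s kernel.  Raises ``ValueError`` if the kernel does not fit.
    """
    f = np.asarray(f, dtype=float)
    k = np.asarray(k, dtype=float)
    m, n = f.shape
    r, s = k.shape
    if r > m or s > n:
        raise ValueError(f"kernel {r}x{s} larger than input {m}x{n}")
    out = np.empty((m - r + 1, n - s + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (f[i : i + r, j : j + s] * k).sum()
    return out


@dataclass(frozen=True)
class PoolSpec:
    """Windowed pooling: ``kind`` in {"max", "avg"}, window r x s, stride t."""

    kind: str
    window: tuple[int, int]
    stride: int = 1

    def __post_init__(self):
        if self.kind not in ("max", "avg"):
            raise ValueError(f"unknown pooling kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def pool(f: np.ndarray, spec: PoolSpec) -> np.ndarray:
    """Windowed max/average pooling of a 2-D grid, windows advancing by stride."""
    f = np.asarray(f, dtype=float)
    m, n = f.shape
    r, s = spec.window
    if r > m or s > n or r < 1 or s < 1:
        raise ValueError(f"window {r}x{s} does not fit input {m}x{n}")
    rows = range(0, m - r + 1, spec.stride)
    cols = range(0, n - s + 1, spec.stride)
    out = np.empty((len(rows), len(cols)))
    for oi, i in enumerate(rows):
        for oj, j in enumerate(cols):
            window = f[i : i + r, j : j + s]
            out[oi, oj] = window.max() if spec.kind == "max" else window.mean()
    return out


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------


class Module:
    """Base class: attribute-based parameter/buffer discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for module in self.modules():
            module.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- checkpoint plumbing -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, array in state.items():
            if name in own:
                if own[name].data.shape != array.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                own[name].data = array.copy()
            elif name in buffers:
                buffers[name][...] = array
            else:
                raise KeyError(f"unexpected entry {name!r} in state dict")
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3/1x1 convolution layer with He-normal initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | tuple[int, int] | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel_size // 2  # "same" for odd kernels at stride 1
        if isinstance(padding, int):
            padding = (padding, padding)
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(
                0.0, scale, size=(out_channels, in_channels, kernel_size, kernel_size)
            ).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.weight.data.shape[1]:
            raise ValueError(
                f"expected {self.weight.data.shape[1]} input channels, "
                f"got {x.data.shape[1]}"
            )
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv1d(Module):
    """1-D channel-mixing convolution (kernel 3, same padding) on (B, C, L)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, in_channels, 1, kernel_size)).astype(
                dtype
            )
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        b, c, length = x.data.shape
        x4 = x.reshape(b, c, 1, length)
        out = conv2d(x4, self.weight, self.bias, 1, (0, self.kernel_size // 2))
        return out.reshape(out.data.shape[0], out.data.shape[1], out.data.shape[3])


class _BatchNorm(Module):
    def __init__(self, num_features: int, param_shape, axes, eps=1e-5, momentum=0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(param_shape, dtype=dtype))
        self.beta = Parameter(np.zeros(param_shape, dtype=dtype))
        self.running_mean = np.zeros(param_shape, dtype=dtype)
        self.running_var = np.ones(param_shape, dtype=dtype)
        self.eps = eps
        self.momentum = momentum
        self.axes = axes

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
            self.axes,
        )


class BatchNorm2d(_BatchNorm):
    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, (1, num_features, 1, 1), (0, 2, 3), **kw)


class BatchNorm1d(_BatchNorm):
    """Normalises (B, C, L) over batch and length."""

    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, (1, num_features, 1), (0, 2), **kw)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(in_features, out_features)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.rate, self.rng, self.training)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


# ---------------------------------------------------------------------------
# backbone units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialBlockConfig:
    in_channels: int
    out_channels: int
    pool: str | None = None  # "max", "avg" or None (2x2 window, stride 2)

    def __post_init__(self):
        if self.out_channels < self.in_channels:
            raise ValueError("spatial blocks widen: out_channels >= in_channels")
        if self.pool not in (None, "max", "avg"):
            raise ValueError(f"unknown pool kind {self.pool!r}")


class SpatialBlock(Module):
    """3x3 conv (same padding) -> batch norm -> ReLU -> optional 2x2 pool."""

    def __init__(self, cfg: SpatialBlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.conv = Conv2d(cfg.in_channels, cfg.out_channels, 3, rng=rng)
        self.bn = BatchNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn(self.conv(x)).relu()
        if self.cfg.pool == "max":
            out = max_pool2x2(out)
        elif self.cfg.pool == "avg":
            out = avg_pool2x2(out)
        return out


@dataclass(frozen=True)
class ResidualBlockConfig:
    in_channels: int
    out_channels: int
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("residual stride must be 1 or 2")

    @property
    def needs_projection(self) -> bool:
        return self.stride != 1 or self.in_channels != self.out_channels


class ResidualBlock(Module):
    """Two 3x3 convolutions with a skip connection.

    Branch = ReLU(conv2(ReLU(BN(conv1(x))))); the second convolution carries
    no batch norm and the final ReLU precedes the addition, so a block with
    all-zero weights is exactly the identity.  When the shape changes the
    shortcut is a strided 1x1 projection convolution.
    """

    def __init__(self, cfg: ResidualBlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.conv1 = Conv2d(cfg.in_channels, cfg.out_channels, 3, stride=cfg.stride, rng=rng)
        self.bn1 = BatchNorm2d(cfg.out_channels)
        self.conv2 = Conv2d(cfg.out_channels, cfg.out_channels, 3, rng=rng)
        self.projection = (
            Conv2d(cfg.in_channels, cfg.out_channels, 1, stride=cfg.stride, padding=0, rng=rng)
            if cfg.needs_projection
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.data.shape[1]}"
            )
        branch = self.conv2(self.bn1(self.conv1(x)).relu()).relu()
        shortcut = x if self.projection is None else self.projection(x)
        return branch + shortcut
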
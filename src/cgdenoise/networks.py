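"""Generator and critic architectures for conditional adversarial denoising.

The generator is fully convolutional: one head convolution, a chain of
residual dense blocks (RDBs) at a fixed channel width, tail fusion
convolutions, and a single-channel output projection squashed into [0, 1]
by a logistic map.  Outer convolutions carry instance normalization and
Leaky ReLU; RDB internals use plain ReLU and no normalization
(normalization inside dense blocks degrades restoration).

Each RDB layer receives the concatenation of the block input and all
earlier internal outputs (dense connectivity); a 1x1 local-fusion
convolution compresses back to the block width and a local residual
addition closes the block, so a block with zeroed fusion weights is an
exact identity map.

The critic channel-concatenates a conditioning image with a candidate
image, runs strided convolutions, and maps the flattened features through
a fully connected layer to one unbounded real score (no sigmoid — a
Wasserstein critic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, InstanceNorm2d, Layer, LeakyReLU, Linear, Module, ReLU, Sigmoid


@dataclass
class RDBConfig:
    n_conv_layers: int = 3
    growth_channels: int = 32
    block_channels: int = 64

    def __post_init__(self) -> None:
        if self.n_conv_layers < 2:
            raise ValueError("n_conv_layers must be >= 2")
        if self.growth_channels < 1:
            raise ValueError("growth_channels must be >= 1")


@dataclass
class GeneratorConfig:
    """Generator hyperparameters.

    ``n_conv_layers_outer`` counts the convolutions outside the RDB chain:
    1 head + (n-2) tail fusion + 1 output projection.  ``in_channels`` is
    2 for the default conditioning stack [enhanced, raw noisy] and 1 when
    conditioning on a single image.
    """

    n_rdbs: int = 6
    n_conv_layers_outer: int = 4
    base_channels: int = 64
    leaky_slope: float = 0.2
    in_channels: int = 2
    use_rdb: bool = True
    rdb: RDBConfig = field(default_factory=RDBConfig)

    def __post_init__(self) -> None:
        if self.n_rdbs < 1:
            raise ValueError("n_rdbs must be >= 1")
        if self.n_conv_layers_outer < 2:
            raise ValueError("n_conv_layers_outer must be >= 2")
        if self.rdb.block_channels != self.base_channels:
            raise ValueError("rdb.block_channels must equal base_channels")


@dataclass
class DiscriminatorConfig:
    """Critic hyperparameters; ``input_size`` fixes the fully connected head."""

    n_conv_stages: int = 4
    base_channels: int = 64
    leaky_slope: float = 0.2
    in_channels: int = 2
    input_size: tuple[int, int] = (70, 70)

    def __post_init__(self) -> None:
        if self.n_conv_stages < 1:
            raise ValueError("n_conv_stages must be >= 1")


class ResidualDenseBlock(Module):
    def __init__(self, cfg: RDBConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.convs: list[Conv2d] = []
        self.acts: list[ReLU] = []
        for i in range(cfg.n_conv_layers):
            self.convs.append(
                Conv2d(cfg.block_channels + i * cfg.growth_channels, cfg.growth_channels, 3, rng=rng)
            )
            self.acts.append(ReLU())
        self.fusion = Conv2d(
            cfg.block_channels + cfg.n_conv_layers * cfg.growth_channels,
            cfg.block_channels,
            kernel_size=1,
            padding=0,
            rng=rng,
        )

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = []
        for i, (c, a) in enumerate(zip(self.convs, self.acts)):
            out.append((f"conv{i}", c))
            out.append((f"act{i}", a))
        out.append(("fusion", self.fusion))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cfg.block_channels:
            raise ValueError(
                f"expected {self.cfg.block_channels} channels, got {x.shape[1]}"
            )
        feats = [x]
        for conv, act in zip(self.convs, self.acts):
            feats.append(act.forward(conv.forward(np.concatenate(feats, axis=1))))
        self._widths = [f.shape[1] for f in feats]
        fused = self.fusion.forward(np.concatenate(feats, axis=1))
        return x + fused

    def backward(self, dy: np.ndarray) -> np.ndarray:
        widths = self._widths
        splits = np.cumsum(widths)[:-1]
        dfeats = list(np.split(self.fusion.backward(dy), splits, axis=1))
        for i in reversed(range(len(self.convs))):
            d = self.acts[i].backward(dfeats[i + 1])
            dcat = self.convs[i].backward(d)
            parts = np.split(dcat, np.cumsum(widths[: i + 1])[:-1], axis=1)
            for j, pj in enumerate(parts):
                dfeats[j] = dfeats[j] + pj
        return dfeats[0] + dy


class PlainBlock(Module):
    """Depth-matched replacement for an RDB: same number of convolutions,
    no dense connectivity, no residual path.  Used by the RDB ablation."""

    def __init__(self, cfg: RDBConfig, rng: np.random.Generator) -> None:
        self.convs = [
            Conv2d(cfg.block_channels, cfg.block_channels, 3, rng=rng)
            for _ in range(cfg.n_conv_layers)
        ]
        self.acts = [ReLU() for _ in range(cfg.n_conv_layers)]
        self.fusion = Conv2d(cfg.block_channels, cfg.block_channels, 1, padding=0, rng=rng)

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = []
        for i, (c, a) in enumerate(zip(self.convs, self.acts)):
            out.append((f"conv{i}", c))
            out.append((f"act{i}", a))
        out.append(("fusion", self.fusion))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for conv, act in zip(self.convs, self.acts):
            x = act.forward(conv.forward(x))
        return self.fusion.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.fusion.backward(dy)
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dy = conv.backward(act.backward(dy))
        return dy


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator | int = 0) -> None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        ch = cfg.base_channels
        self.head = Conv2d(cfg.in_channels, ch, 3, rng=rng)
        self.head_norm = InstanceNorm2d(ch)
        self.head_act = LeakyReLU(cfg.leaky_slope)
        block_cls = ResidualDenseBlock if cfg.use_rdb else PlainBlock
        self.blocks = [block_cls(cfg.rdb, rng) for _ in range(cfg.n_rdbs)]
        self.tails = []
        for _ in range(cfg.n_conv_layers_outer - 2):
            self.tails.append(
                (Conv2d(ch, ch, 3, rng=rng), InstanceNorm2d(ch), LeakyReLU(cfg.leaky_slope))
            )
        self.proj = Conv2d(ch, 1, 3, rng=rng)
        self.out_act = Sigmoid()

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = [("head", self.head), ("head_norm", self.head_norm), ("head_act", self.head_act)]
        for b, block in enumerate(self.blocks):
            out.extend((f"block{b}.{n}", layer) for n, layer in block.named_layers())
        for t, (conv, norm, act) in enumerate(self.tails):
            out.extend([(f"tail{t}", conv), (f"tail{t}_norm", norm), (f"tail{t}_act", act)])
        out.extend([("proj", self.proj), ("out_act", self.out_act)])
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a conditioning stack (N, in_channels, H, W) to (N, 1, H, W) in [0, 1]."""
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        h = self.head_act.forward(self.head_norm.forward(self.head.forward(x)))
        for block in self.blocks:
            h = block.forward(h)
        for conv, norm, act in self.tails:
            h = act.forward(norm.forward(conv.forward(h)))
        return self.out_act.forward(self.proj.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.proj.backward(self.out_act.backward(dy))
        for conv, norm, act in reversed(self.tails):
            d = conv.backward(norm.backward(act.backward(d)))
        for block in reversed(self.blocks):
            d = block.backward(d)
        return self.head.backward(self.head_norm.backward(self.head_act.backward(d)))


def _strided_out(size: int) -> int:
    # k=3, stride=2, pad=1
    return (size - 1) // 2 + 1


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator | int = 0) -> None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.stages = []
        h, w = cfg.input_size
        in_ch = cfg.in_channels
        for i in range(cfg.n_conv_stages):
            out_ch = cfg.base_channels * 2**i
            conv = Conv2d(in_ch, out_ch, 3, stride=2, padding=1, rng=rng)
            norm = InstanceNorm2d(out_ch) if i > 0 else None  # no norm on first stage
            act = LeakyReLU(cfg.leaky_slope)
            self.stages.append((conv, norm, act))
            in_ch = out_ch
            h, w = _strided_out(h), _strided_out(w)
        self.flat_features = in_ch * h * w
        self.fc = Linear(self.flat_features, 1, rng=rng)

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = []
        for i, (conv, norm, act) in enumerate(self.stages):
            out.append((f"stage{i}", conv))
            if norm is not None:
                out.append((f"stage{i}_norm", norm))
            out.append((f"stage{i}_act", act))
        out.append(("fc", self.fc))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map (N, in_channels, H, W) to a batch of unbounded scores (N,)."""
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, H, W), got {x.shape}")
        if tuple(x.shape[2:]) != tuple(self.cfg.input_size):
            raise ValueError(
                f"critic was built for input size {self.cfg.input_size}, got {x.shape[2:]}"
            )
        for conv, norm, act in self.stages:
            x = conv.forward(x)
            if norm is not None:
                x = norm.forward(x)
            x = act.forward(x)
        self._feat_shape = x.shape
        return self.fc.forward(x.reshape(x.shape[0], -1))[:, 0]

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        d = self.fc.backward(np.asarray(dscore).reshape(-1, 1)).reshape(self._feat_shape)
        for conv, norm, act in reversed(self.stages):
            d = act.backward(d)
            if norm is not None:
                d = norm.backward(d)
            d = conv.backward(d)
        return d

    def score(self, conditioning: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        """Score channel-concatenated (conditioning, candidate) pairs."""
        if conditioning.shape != candidate.shape:
            raise ValueError("conditioning and candidate must have equal dimensions")
        return self.forward(np.concatenate([conditioning, candidate], axis=1))

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d score_i / d x_i for each sample i (param grads are discarded)."""
        self.forward(x)
        dx = self.backward(np.ones(x.shape[0]))
        self.zero_grad()
        return dx


def _as_stack(images) -> np.ndarray:
    """Accept a 2-D image, a list of 2-D images, or an (C, H, W)/(N, C, H, W) array."""
    if isinstance(images, (list, tuple)):
        arr = np.stack([np.asarray(im, dtype=np.float64) for im in images], axis=0)
    else:
        arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as an image stack")
    return arr


def rdb_forward(block: ResidualDenseBlock, features: np.ndarray) -> np.ndarray:
    """Run one residual dense block on an (N, C, H, W) feature tensor."""
    return block.forward(np.asarray(features, dtype=np.float64))


def generator_forward(generator: Generator, conditioning) -> np.ndarray:
    """Run the generator on a conditioning stack; returns a 2-D image in [0, 1]."""
    out = generator.forward(_as_stack(conditioning))
    return out[0, 0]


def discriminator_forward(
    discriminator: Discriminator, conditioning: np.ndarray, candidate: np.ndarray
) -> float:
    """Score one (conditioning, candidate) image pair; returns a finite real."""
    cond = _as_stack(conditioning)
    cand = _as_stack(candidate)
    return float(discriminator.score(cond, cand)[0])
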
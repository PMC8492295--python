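"""Alternating adversarial training of the conditional denoiser.

Each step draws random, spatially aligned crops from the paired samples,
updates the Wasserstein critic on {conditioning, clean} vs
{conditioning, generated} pairs, enforces the Lipschitz constraint, and
then updates the generator on the hybrid L1 + adversarial objective.
The generator conditions on a 2-channel stack [gradient-enhanced image,
raw noisy image]; the critic conditions on the enhanced image alone, per
the pairs x = {enhanced, clean} and x' = {enhanced, denoised}.

Everything is a pure function of the seed: dataset order, crop offsets,
and parameter initialization all derive from one ``SeedSequence``, and a
checkpoint stores the full random-stream state so a resumed run follows
the identical trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .gradients import InvalidStateError, enhance
from .image import validate_image
from .losses import (
    LossReport,
    LossWeights,
    clip_weights,
    critic_objective,
    generator_adversarial,
    reconstruction_loss,
    total_generator_loss,
)
from .networks import Discriminator, DiscriminatorConfig, Generator, GeneratorConfig, RDBConfig
from .nn import Adam
from .synthetic import PairedSample

#: Smallest image the full-image inference path accepts (approximate
#: receptive-field floor of the generator).
MIN_DENOISE_SIZE = 16

LOSS_MODES = ("l1", "wgan", "l1+wgan")


@dataclass
class TrainConfig:
    epochs: int
    learning_rate: float = 2e-3
    batch_size: int = 1
    patch_size: int = 70
    lambda1: float = 0.5
    seed: int = 0
    betas: tuple[float, float] = (0.5, 0.9)
    lipschitz_mode: str = "clip"
    clip_bound: float = 0.01
    gp_coefficient: float = 10.0
    n_critic: int = 1
    loss_mode: str = "l1+wgan"
    use_gradient_enhancement: bool = True
    enhancement_scale: float = 1.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.patch_size < 1 or self.n_critic < 1:
            raise ValueError("batch_size, patch_size and n_critic must be >= 1")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.lipschitz_mode not in ("clip", "gradient_penalty"):
            raise ValueError("lipschitz_mode must be 'clip' or 'gradient_penalty'")
        # derive dependent architecture fields from the training setup
        gen_in = 2 if self.use_gradient_enhancement else 1
        if self.generator.in_channels != gen_in:
            self.generator = dataclasses.replace(self.generator, in_channels=gen_in)
        patch = (self.patch_size, self.patch_size)
        if self.discriminator.input_size != patch or self.discriminator.in_channels != 2:
            self.discriminator = dataclasses.replace(
                self.discriminator, input_size=patch, in_channels=2
            )


def config_to_dict(config: TrainConfig) -> dict:
    d = dataclasses.asdict(config)
    d["betas"] = list(d["betas"])
    d["discriminator"]["input_size"] = list(d["discriminator"]["input_size"])
    return d


def config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    if "generator" in d and isinstance(d["generator"], dict):
        g = dict(d["generator"])
        if "rdb" in g and isinstance(g["rdb"], dict):
            g["rdb"] = RDBConfig(**g["rdb"])
        d["generator"] = GeneratorConfig(**g)
    if "discriminator" in d and isinstance(d["discriminator"], dict):
        disc = dict(d["discriminator"])
        if "input_size" in disc:
            disc["input_size"] = tuple(disc["input_size"])
        d["discriminator"] = DiscriminatorConfig(**disc)
    if "betas" in d:
        d["betas"] = tuple(d["betas"])
    return TrainConfig(**d)


@dataclass
class TrainState:
    generator: Generator
    discriminator: Discriminator
    opt_g: Adam
    opt_d: Adam
    rng: np.random.Generator
    config: TrainConfig
    epoch: int = 0
    step: int = 0
    history: list[LossReport] = field(default_factory=list)


def init_state(config: TrainConfig) -> TrainState:
    """Fresh networks, optimizers and random stream derived from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    ss_g, ss_d, ss_stream = ss.spawn(3)
    generator = Generator(config.generator, np.random.default_rng(ss_g))
    discriminator = Discriminator(config.discriminator, np.random.default_rng(ss_d))
    return TrainState(
        generator=generator,
        discriminator=discriminator,
        opt_g=Adam(generator, config.learning_rate, config.betas),
        opt_d=Adam(discriminator, config.learning_rate, config.betas),
        rng=np.random.default_rng(ss_stream),
        config=config,
    )


def ensure_enhanced(sample: PairedSample, scale: float = 1.0) -> PairedSample:
    """Compute and cache the conditioning image (depends only on the noisy image)."""
    if sample.enhanced is None:
        sample.enhanced = enhance(sample.noisy, scale=scale)
    return sample


def extract_patch(sample: PairedSample, patch_size: int, rng: np.random.Generator) -> PairedSample:
    """Crop clean/noisy/enhanced at one shared random offset (alignment preserved)."""
    h, w = sample.clean.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image size {sample.clean.shape}")
    i = int(rng.integers(0, h - patch_size + 1))
    j = int(rng.integers(0, w - patch_size + 1))
    sl = (slice(i, i + patch_size), slice(j, j + patch_size))
    return PairedSample(
        clean=sample.clean[sl].copy(),
        noisy=sample.noisy[sl].copy(),
        enhanced=None if sample.enhanced is None else sample.enhanced[sl].copy(),
        spec=sample.spec,
    )


def _batch_arrays(batch: list[PairedSample], config: TrainConfig):
    clean = np.stack([s.clean for s in batch])[:, None]
    noisy = np.stack([s.noisy for s in batch])[:, None]
    if config.use_gradient_enhancement:
        for s in batch:
            if s.enhanced is None:
                raise InvalidStateError("sample is missing its enhanced conditioning image")
        enhanced = np.stack([s.enhanced for s in batch])[:, None]
        cond_g = np.concatenate([enhanced, noisy], axis=1)
        cond_d = enhanced
    else:
        cond_g = noisy
        cond_d = noisy
    return clean, cond_g, cond_d


def train_step(
    state: TrainState, batch: list[PairedSample], config: TrainConfig
) -> tuple[TrainState, LossReport]:
    """One critic update (x n_critic) followed by one generator update."""
    if len(batch) != config.batch_size:
        raise ValueError(f"batch size {len(batch)} does not match config {config.batch_size}")
    clean, cond_g, cond_d = _batch_arrays(batch, config)
    n = clean.shape[0]
    use_adv = config.loss_mode in ("wgan", "l1+wgan")
    use_l1 = config.loss_mode in ("l1", "l1+wgan")
    lam = config.lambda1 if use_l1 else 0.0
    weights = LossWeights(lam)

    fake = state.generator.forward(cond_g)  # caches retained for the G update

    wgan_d = 0.0
    if use_adv:
        for _ in range(config.n_critic):
            state.discriminator.zero_grad()
            s_real = state.discriminator.score(cond_d, clean)
            d_real = np.full(n, -1.0 / n)  # critic minimizes the negated objective
            if config.lipschitz_mode == "gradient_penalty":
                # First-order Lipschitz surrogate along the real-fake chord:
                # penalize |D(real)-D(fake)| / ||real-fake|| above 1.
                s_fake_pre = state.discriminator.score(cond_d, fake)
                dist = np.sqrt(((clean - fake) ** 2).sum(axis=(1, 2, 3))) + 1e-12
                ratio = (s_real - s_fake_pre) / dist
                excess = np.maximum(np.abs(ratio) - 1.0, 0.0)
                dratio = config.gp_coefficient * 2.0 * excess * np.sign(ratio) / (n * dist)
                d_real = d_real + dratio
                d_fake_extra = -dratio
                state.discriminator.score(cond_d, clean)  # restore the real-pair cache
            else:
                d_fake_extra = np.zeros(n)
            state.discriminator.backward(d_real)
            s_fake = state.discriminator.score(cond_d, fake)
            state.discriminator.backward(np.full(n, 1.0 / n) + d_fake_extra)
            wgan_d = critic_objective(s_real, s_fake)
            state.opt_d.step()
            if config.lipschitz_mode == "clip":
                clip_weights(state.discriminator, config.clip_bound)

    # generator update
    recon = reconstruction_loss(clean, fake)
    dfake = np.zeros_like(fake)
    if use_l1:
        dfake += lam * np.sign(fake - clean) / fake.size
    wgan_g = 0.0
    if use_adv:
        s_fake2 = state.discriminator.score(cond_d, fake)
        wgan_g = generator_adversarial(s_fake2)
        dx = state.discriminator.backward(np.full(n, -1.0 / n))
        state.discriminator.zero_grad()  # the critic is not stepped here
        dfake += dx[:, -1:]  # candidate channel
    state.generator.zero_grad()
    state.generator.backward(dfake)
    state.opt_g.step()

    report = LossReport(
        recon=recon,
        wgan_g=wgan_g,
        wgan_d=wgan_d,
        total_g=total_generator_loss(wgan_g, recon, weights),
    )
    state.history.append(report)
    state.step += 1
    return state, report


def fit(
    dataset: list[PairedSample],
    config: TrainConfig,
    state: TrainState | None = None,
    log_path=None,
    checkpoint_path=None,
    checkpoint_interval: int | None = None,
) -> TrainState:
    """Run ``epochs`` passes of shuffled, freshly cropped train steps.

    Pass a loaded ``state`` to resume; training continues from
    ``state.epoch`` to ``config.epochs`` on the same trajectory.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if config.use_gradient_enhancement:
        for s in dataset:
            ensure_enhanced(s, scale=config.enhancement_scale)
    if state is None:
        state = init_state(config)
    n = len(dataset)
    log_f = open(log_path, "a") if log_path else None
    try:
        for epoch in range(state.epoch, config.epochs):
            order = state.rng.permutation(n)
            epoch_reports = []
            for start in range(0, n - config.batch_size + 1, config.batch_size):
                batch = [
                    extract_patch(dataset[i], config.patch_size, state.rng)
                    for i in order[start : start + config.batch_size]
                ]
                _, report = train_step(state, batch, config)
                epoch_reports.append(report)
            state.epoch = epoch + 1
            if log_f is not None:
                rec = {
                    "epoch": state.epoch,
                    "step": state.step,
                    "recon": float(np.mean([r.recon for r in epoch_reports])),
                    "wgan_g": float(np.mean([r.wgan_g for r in epoch_reports])),
                    "wgan_d": float(np.mean([r.wgan_d for r in epoch_reports])),
                    "total_g": float(np.mean([r.total_g for r in epoch_reports])),
                }
                log_f.write(json.dumps(rec) + "\n")
                log_f.flush()
            if (
                checkpoint_path is not None
                and checkpoint_interval
                and state.epoch % checkpoint_interval == 0
            ):
                save_checkpoint(state, checkpoint_path)
    finally:
        if log_f is not None:
            log_f.close()
    return state


def denoise(state: TrainState, noisy: np.ndarray) -> np.ndarray:
    """Denoise a full image (no cropping): enhancement -> generator forward."""
    arr = validate_image(noisy, "noisy")
    if min(arr.shape) < MIN_DENOISE_SIZE:
        raise ValueError(f"image sides must be >= {MIN_DENOISE_SIZE} for inference")
    if state.config.use_gradient_enhancement:
        enhanced = enhance(arr, scale=state.config.enhancement_scale)
        stack = np.stack([enhanced, arr])[None]
    else:
        stack = arr[None, None]
    return state.generator.forward(stack)[0, 0]


def save_checkpoint(state: TrainState, path) -> None:
    """Serialize parameters, optimizer moments, rng stream and history."""
    payload: dict[str, np.ndarray] = {}
    for key, layer, p in state.generator.param_items():
        payload[f"g::{key}"] = layer.params[p]
    for key, layer, p in state.discriminator.param_items():
        payload[f"d::{key}"] = layer.params[p]
    for tag, opt in (("og", state.opt_g), ("od", state.opt_d)):
        sd = opt.state_dict()
        payload[f"{tag}::t"] = np.asarray(sd["t"])
        for k, v in sd["m"].items():
            payload[f"{tag}m::{k}"] = v
        for k, v in sd["v"].items():
            payload[f"{tag}v::{k}"] = v
    payload["epoch"] = np.asarray(state.epoch)
    payload["step"] = np.asarray(state.step)
    payload["history"] = np.asarray(
        [[r.recon, r.wgan_g, r.wgan_d, r.total_g] for r in state.history]
    ).reshape(-1, 4)
    payload["config_json"] = np.asarray(json.dumps(config_to_dict(state.config)))
    payload["rng_state_json"] = np.asarray(json.dumps(state.rng.bit_generator.state))
    np.savez(path, **payload)


def load_checkpoint(path) -> TrainState:
    with np.load(path, allow_pickle=False) as data:
        config = config_from_dict(json.loads(str(data["config_json"])))
        state = init_state(config)
        g_state = {k[len("g::") :]: data[k] for k in data.files if k.startswith("g::")}
        d_state = {k[len("d::") :]: data[k] for k in data.files if k.startswith("d::")}
        state.generator.load_state_dict(g_state)
        state.discriminator.load_state_dict(d_state)
        for tag, opt in (("og", state.opt_g), ("od", state.opt_d)):
            opt.load_state_dict(
                {
                    "t": int(data[f"{tag}::t"]),
                    "m": {k[len(tag) + 3 :]: data[k] for k in data.files if k.startswith(f"{tag}m::")},
                    "v": {k[len(tag) + 3 :]: data[k] for k in data.files if k.startswith(f"{tag}v::")},
                }
            )
        state.epoch = int(data["epoch"])
        state.step = int(data["step"])
        state.history = [
            LossReport(recon=row[0], wgan_g=row[1], wgan_d=row[2], total_g=row[3])
            for row in data["history"]
        ]
        state.rng.bit_generator.state = json.loads(str(data["rng_state_json"]))
    return state
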
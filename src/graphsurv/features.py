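"""Per-patch feature extraction with contrastive pretraining.

Patches are embedded by a small convolutional encoder trained with the
normalized temperature-scaled cross-entropy (NT-Xent) objective: two
augmented views of each patch form a positive pair, every other view in the
batch is a negative, and the encoder plus a throwaway 2-layer projection
head are optimized to pull positives together on the unit hypersphere. The
projection head is discarded for feature extraction.

Augmentations follow the usual contrastive recipe — random color jitter,
random Gaussian blur, random crop resized back to the original size — with
configurable magnitudes.

Backbones: ``small_cnn`` (3 strided conv blocks, the default used
throughout the test suite) and deeper residual variants ``resnet18`` /
``resnet50`` built from the same numpy layers. ``pretrained_source`` may be
``random`` or ``contrastive``; no external pretrained weights ship with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .errors import ConfigurationError
from .nn import Adam, Linear, Module, conv2d, glorot_uniform, pad_hw

__all__ = [
    "AugmentationSpec", "EncoderConfig", "augment", "contrastive_loss",
    "encode_patches", "pretrain_encoder", "build_encoder",
    "save_encoder", "load_encoder",
]


@dataclass
class AugmentationSpec:
    color_jitter_strength: float = 0.4
    blur_sigma_range: tuple[float, float] = (0.1, 1.0)
    crop_scale_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.color_jitter_strength < 0:
            raise ConfigurationError("color_jitter_strength must be >= 0")
        for name in ("blur_sigma_range", "crop_scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        if not (0 < self.crop_scale_range[0] <= self.crop_scale_range[1] <= 1):
            raise ConfigurationError("crop_scale_range must lie in (0, 1]")


@dataclass
class EncoderConfig:
    backbone: str = "small_cnn"
    output_dim: int = 32
    temperature: float = 0.5
    pretrained_source: str = "random"
    seed: int = 0

    def validate(self) -> None:
        if self.backbone not in ("small_cnn", "resnet18", "resnet50"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.pretrained_source not in ("random", "contrastive"):
            raise ConfigurationError(
                f"pretrained_source must be 'random' or 'contrastive' "
                f"(no bundled external weights), got {self.pretrained_source!r}")


def _to_float(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.dtype == np.uint8:
        return patch.astype(np.float64) / 255.0
    return patch.astype(np.float64)


def augment(patch: np.ndarray, spec: AugmentationSpec,
            draw: np.random.Generator) -> np.ndarray:
    """One stochastic view of a square RGB patch, same spatial size out."""
    from scipy.ndimage import gaussian_filter
    from skimage.color import hsv2rgb, rgb2hsv
    from skimage.transform import resize

    spec.validate()
    x = _to_float(patch)
    if x.shape[0] != x.shape[1]:
        raise ConfigurationError("patch must be square")
    side = x.shape[0]
    s = spec.color_jitter_strength
    if s > 0:
        brightness = draw.uniform(max(0.0, 1 - s), 1 + s)
        contrast = draw.uniform(max(0.0, 1 - s), 1 + s)
        saturation = draw.uniform(max(0.0, 1 - s), 1 + s)
        hue = draw.uniform(-0.1 * s, 0.1 * s)
        x = np.clip(x * brightness, 0, 1)
        x = np.clip((x - x.mean()) * contrast + x.mean(), 0, 1)
        hsv = rgb2hsv(x)
        hsv[..., 1] = np.clip(hsv[..., 1] * saturation, 0, 1)
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        x = hsv2rgb(hsv)
    sigma = draw.uniform(*spec.blur_sigma_range)
    if sigma > 0.01:
        x = gaussian_filter(x, sigma=(sigma, sigma, 0))
    scale = draw.uniform(*spec.crop_scale_range)
    if scale < 1.0:
        crop = max(1, int(round(side * scale)))
        r0 = draw.integers(0, side - crop + 1)
        c0 = draw.integers(0, side - crop + 1)
        x = resize(x[r0:r0 + crop, c0:c0 + crop], (side, side, 3),
                   order=1, anti_aliasing=False)
    return np.clip(x, 0.0, 1.0)


def contrastive_loss(embeddings, temperature: float = 0.5):
    """NT-Xent over paired views.

    Rows 2k and 2k+1 are a positive pair. Rows are unit-normalized
    internally. Accepts an ndarray (returns float) or a ``Tensor`` (returns
    a scalar ``Tensor``).
    """
    is_tensor = isinstance(embeddings, Tensor)
    z = embeddings if is_tensor else Tensor(np.asarray(embeddings, float))
    n2 = z.shape[0]
    if n2 % 2 != 0 or n2 < 4:
        raise ConfigurationError(
            "need an even number of rows and at least 2 pairs (no negatives "
            "otherwise)")
    norm = (z * z).sum(axis=1, keepdims=True).sqrt().clamp_min(1e-12)
    z = z / norm
    sim = (z @ z.T) * (1.0 / temperature)
    diag_mask = np.where(np.eye(n2, dtype=bool), -1e30, 0.0)
    sim = sim + Tensor(diag_mask)
    row_max = sim.data.max(axis=1, keepdims=True)            # constant shift
    e = (sim - Tensor(row_max)).exp()
    log_denom = e.sum(axis=1).log() + Tensor(row_max.ravel())
    idx = np.arange(n2)
    pos = idx ^ 1                                            # partner of each row
    pos_sim = sim[idx, pos]
    loss = (log_denom - pos_sim).mean()
    return loss if is_tensor else float(loss.data)


class _ConvBlock(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 2, kernel: int = 3, padding: int = 0):
        self.weight = Tensor(glorot_uniform(rng, (kernel, kernel, cin, cout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = pad_hw(x, self.padding)
        return conv2d(x, self.weight, self.bias, self.stride).elu()


class _ResBlock(Module):
    """Two same-padded stride-1 convs with a residual add."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.c1 = _ConvBlock(ch, ch, rng, stride=1, padding=1)
        self.c2 = _ConvBlock(ch, ch, rng, stride=1, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x)) + x


class Encoder(Module):
    """Conv backbone + linear feature layer + projection head."""

    def __init__(self, config: EncoderConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = {"small_cnn": (16, 32, 64), "resnet18": (16, 32, 64),
                  "resnet50": (32, 64, 128)}[config.backbone]
        n_res = {"small_cnn": 0, "resnet18": 1, "resnet50": 2}[config.backbone]
        blocks: list[Module] = []
        cin = 3
        for wdt in widths:
            blocks.append(_ConvBlock(cin, wdt, rng, stride=2))
            for _ in range(n_res):
                blocks.append(_ResBlock(wdt, rng))
            cin = wdt
        self.blocks = blocks
        self.feat = Linear(widths[-1], config.output_dim, rng)
        self.proj1 = Linear(config.output_dim, config.output_dim, rng)
        self.proj2 = Linear(config.output_dim, config.output_dim, rng)

    def backbone(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        pooled = x.mean(axis=(1, 2))          # global average pool -> (N, ch)
        return self.feat(pooled)

    def forward(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def project(self, x: Tensor) -> Tensor:
        return self.proj2(self.proj1(self.backbone(x)).relu())


def build_encoder(config: EncoderConfig) -> Encoder:
    return Encoder(config)


def _stack(patches) -> np.ndarray:
    arr = np.stack([_to_float(p) for p in patches], axis=0)
    return arr - 0.5  # center around zero


def encode_patches(patches, encoder: Encoder, batch_size: int = 64
                   ) -> np.ndarray:
    """Deterministic N x C feature matrix, row i for patch i."""
    if len(patches) == 0:
        raise ConfigurationError("no patches to encode")
    outs = []
    with no_grad():
        for i in range(0, len(patches), batch_size):
            batch = _stack(patches[i:i + batch_size])
            outs.append(encoder.backbone(Tensor(batch)).data)
    return np.concatenate(outs, axis=0).astype(np.float32)


def pretrain_encoder(patch_source, encoder_config: EncoderConfig,
                     augmentation_spec: AugmentationSpec, epochs: int = 5,
                     batch_size: int = 16, seed: int = 0,
                     lr: float = 1e-3) -> Encoder:
    """Contrastive pretraining; returns the trained encoder.

    ``patch_source`` is a sequence of RGB patches. ``epochs == 0`` returns
    the freshly initialized encoder untouched.
    """
    patches = list(patch_source)
    if len(patches) == 0:
        raise ConfigurationError("empty patch source")
    if len(patches) < 2 * batch_size:
        raise ConfigurationError(
            f"need >= {2 * batch_size} patches for batch_size={batch_size}, "
            f"got {len(patches)}")
    encoder = build_encoder(encoder_config)
    if epochs == 0:
        return encoder
    rng = np.random.default_rng(seed)
    opt = Adam(encoder.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(patches))
        for start in range(0, len(order) - batch_size + 1, batch_size):
            batch_idx = order[start:start + batch_size]
            views = []
            for j in batch_idx:
                views.append(augment(patches[j], augmentation_spec, rng))
                views.append(augment(patches[j], augmentation_spec, rng))
            z = encoder.project(Tensor(_stack(views)))
            loss = contrastive_loss(z, encoder_config.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return encoder


def save_encoder(encoder: Encoder, path) -> None:
    import json

    cfg = vars(encoder.config).copy()
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(),
                                            dtype=np.uint8),
             **encoder.state_dict())


def load_encoder(path) -> Encoder:
    import json

    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    encoder = Encoder(EncoderConfig(**cfg))
    encoder.load_state_dict(state)
    return encoder
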
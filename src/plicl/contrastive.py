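"""Contrastive training of the texture encoder and sliding-window inference.

Training follows the SimCLR recipe with the InfoNCE objective: per step, N
fresh positive pairs are drawn on the fly by spatial context sampling, both
members are independently augmented with the PLI-specific policy, encoded as
(IT, r cos 2phi, r sin 2phi) channels, standardized by running per-channel
statistics (accumulated over the first ``standardization_batches`` batches
and then frozen, which also makes inference deterministic), and passed
through the encoder and projection head.  Projections are L2-normalized and
contrasted under temperature-scaled cosine similarity; parameters are
optimized with Adam.

After training, the projection head is discarded and whole sections are
converted into feature maps by tiling the parameter maps (tiles of 128 px
with 50 percent overlap in the reference protocol) and extracting one pooled
feature vector per tile, without augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import h5py
import numpy as np

from . import nn
from .augment import AugmentationPolicy, random_policy_apply
from .encoder import ProjectionHead, ResNetEncoder
from .physics import ParameterMaps, channel_encode
from .sampling import SamplingMode, extract_pair, pair_stream
from .synthdata import SectionStack

__all__ = [
    "EncoderConfig",
    "FeatureMap",
    "RunningStandardizer",
    "TrainedModel",
    "build_encoder",
    "desk_config",
    "info_nce_loss",
    "train",
    "infer_feature_map",
]


@dataclass
class EncoderConfig:
    """Architecture and optimization hyperparameters.

    Reference defaults: 1/8-width encoder (256-d features), projection head
    90 -> 32, temperature 0.5, 512 pairs per batch, Adam with learning rate
    1e-3 and weight decay 1e-6, input standardization frozen after 1024
    batches.  Desk-scale runs override ``batch_pairs`` and
    ``standardization_batches``.
    """

    width_fraction: float = 0.125
    input_channels: int = 3
    projection_hidden: int = 90
    projection_out: int = 32
    temperature: float = 0.5
    batch_pairs: int = 512
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    standardization_batches: int = 1024

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if min(self.projection_hidden, self.projection_out, self.batch_pairs) <= 0:
            raise ValueError("dimensions must be positive")


def desk_config() -> EncoderConfig:
    """Single-CPU desk-scale training profile.

    Batch of 64 pairs with standardization frozen after 16 batches, and a
    learning rate of 3e-3: the reference rate of 1e-3 belongs to the
    512-pair reference batch, and the small-batch profile trains markedly
    faster at the higher rate while remaining stable.
    """
    return EncoderConfig(batch_pairs=64, standardization_batches=16, learning_rate=3e-3)


def build_encoder(cfg: EncoderConfig, rng: np.random.Generator | None = None) -> ResNetEncoder:
    """Instantiate the width-scaled residual encoder described by ``cfg``."""
    return ResNetEncoder(cfg.width_fraction, cfg.input_channels, rng=rng)


def info_nce_loss(projections: np.ndarray, pair_index: np.ndarray, tau: float = 0.5) -> float:
    """InfoNCE loss of a batch of 2N projection vectors (cosine similarity).

    ``pair_index[i]`` is the positive partner of sample ``i``.  Vectors are
    L2-normalized internally, so the similarity is the cosine.  Returns the
    symmetrized mean over all pairs; zero when N = 1 (no negatives).
    """
    z = nn.l2_normalize_rows(nn.Tensor(np.asarray(projections, dtype=np.float32)))
    return float(nn.nt_xent_loss(z, np.asarray(pair_index), tau).data)


class RunningStandardizer:
    """Per-channel Welford mean/std, frozen after a fixed number of batches."""

    def __init__(self, channels: int, freeze_after: int) -> None:
        self.freeze_after = freeze_after
        self.count = 0.0
        self.batches_seen = 0
        self.mean = np.zeros(channels)
        self.m2 = np.zeros(channels)

    @property
    def frozen(self) -> bool:
        return self.batches_seen >= self.freeze_after

    def update(self, batch: np.ndarray) -> None:
        """Accumulate statistics from a (B, C, H, W) batch unless frozen."""
        if self.frozen:
            return
        flat = batch.transpose(1, 0, 2, 3).reshape(batch.shape[1], -1)
        n = flat.shape[1]
        b_mean = flat.mean(axis=1)
        b_m2 = ((flat - b_mean[:, None]) ** 2).sum(axis=1)
        delta = b_mean - self.mean
        tot = self.count + n
        self.mean = self.mean + delta * n / tot
        self.m2 = self.m2 + b_m2 + delta**2 * self.count * n / tot
        self.count = tot
        self.batches_seen += 1

    @property
    def std(self) -> np.ndarray:
        if self.count < 2:
            return np.ones_like(self.mean)
        return np.sqrt(np.maximum(self.m2 / self.count, 1e-12))

    def apply(self, batch: np.ndarray) -> np.ndarray:
        return (batch - self.mean[None, :, None, None]) / self.std[None, :, None, None]

    def state(self) -> dict[str, np.ndarray]:
        return {
            "mean": self.mean,
            "m2": self.m2,
            "count": np.array(self.count),
            "batches_seen": np.array(self.batches_seen),
            "freeze_after": np.array(self.freeze_after),
        }

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray]) -> "RunningStandardizer":
        out = cls(len(state["mean"]), int(state["freeze_after"]))
        out.mean = np.asarray(state["mean"], dtype=float)
        out.m2 = np.asarray(state["m2"], dtype=float)
        out.count = float(state["count"])
        out.batches_seen = int(state["batches_seen"])
        return out


@dataclass
class FeatureMap:
    """Grid of per-tile feature vectors for one section.

    ``features`` has shape (H', W', D); tile centers sit at
    ``origin + index * stride`` in section pixel coordinates.  ``tile_labels``
    optionally holds the modal mask value of each tile footprint.
    """

    features: np.ndarray
    tile_px: int
    stride_px: int
    section: int = 0
    pixel_size_um: float = 1.3
    tile_labels: np.ndarray | None = None

    @property
    def origin(self) -> float:
        return (self.tile_px - 1) / 2.0

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.features.shape[:2]

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        hh, ww = self.grid_shape
        ys = self.origin + self.stride_px * np.arange(hh)
        xs = self.origin + self.stride_px * np.arange(ww)
        return ys, xs

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(str(path), "w") as f:
            f.create_dataset("features", data=self.features.astype(np.float32))
            if self.tile_labels is not None:
                f.create_dataset("tile_labels", data=self.tile_labels.astype(np.int8))
            f.attrs.update(
                tile_px=self.tile_px,
                stride_px=self.stride_px,
                section=self.section,
                pixel_size_um=self.pixel_size_um,
            )

    @classmethod
    def load_h5(cls, path: str | Path) -> "FeatureMap":
        with h5py.File(str(path), "r") as f:
            return cls(
                features=f["features"][()],
                tile_px=int(f.attrs["tile_px"]),
                stride_px=int(f.attrs["stride_px"]),
                section=int(f.attrs["section"]),
                pixel_size_um=float(f.attrs["pixel_size_um"]),
                tile_labels=f["tile_labels"][()] if "tile_labels" in f else None,
            )


@dataclass
class TrainedModel:
    """Frozen encoder plus the input standardization used to train it."""

    encoder: ResNetEncoder
    head: ProjectionHead
    standardizer: RunningStandardizer
    config: EncoderConfig
    loss_curve: list[float] = dataclass_field(default_factory=list)
    val_curve: list[float] = dataclass_field(default_factory=list)

    def encode(self, patches: list[ParameterMaps], batch_size: int = 64) -> np.ndarray:
        """Pooled feature vectors for unaugmented patches (eval mode)."""
        self.encoder.eval()
        feats = []
        for i in range(0, len(patches), batch_size):
            x = np.stack([channel_encode(p) for p in patches[i : i + batch_size]])
            x = self.standardizer.apply(x).astype(np.float32)
            feats.append(self.encoder(nn.Tensor(x)).data)
        return np.concatenate(feats, axis=0)

    def save(self, path: str | Path) -> None:
        state = self.encoder.state_dict("encoder.")
        state.update(self.head.state_dict("head."))
        state.update({f"standardizer.{k}": v for k, v in self.standardizer.state().items()})
        with h5py.File(str(path), "w") as f:
            for k, v in state.items():
                f.create_dataset(k, data=np.asarray(v))
            f.attrs["width_fraction"] = self.config.width_fraction
            f.attrs["input_channels"] = self.config.input_channels
            f.attrs["projection_hidden"] = self.config.projection_hidden
            f.attrs["projection_out"] = self.config.projection_out
            f.attrs["temperature"] = self.config.temperature
            f.create_dataset("loss_curve", data=np.asarray(self.loss_curve))
            f.create_dataset("val_curve", data=np.asarray(self.val_curve))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with h5py.File(str(path), "r") as f:
            cfg = EncoderConfig(
                width_fraction=float(f.attrs["width_fraction"]),
                input_channels=int(f.attrs["input_channels"]),
                projection_hidden=int(f.attrs["projection_hidden"]),
                projection_out=int(f.attrs["projection_out"]),
                temperature=float(f.attrs["temperature"]),
            )
            encoder = build_encoder(cfg)
            head = ProjectionHead(encoder.feature_dim, cfg.projection_hidden, cfg.projection_out)
            state = {k: f[k][()] for k in f.keys() if k not in ("loss_curve", "val_curve")}
            encoder.load_state_dict({k[len("encoder.") :]: v for k, v in state.items() if k.startswith("encoder.")})
            head.load_state_dict({k[len("head.") :]: v for k, v in state.items() if k.startswith("head.")})
            std = RunningStandardizer.from_state(
                {k[len("standardizer.") :]: v for k, v in state.items() if k.startswith("standardizer.")}
            )
            model = cls(encoder, head, std, cfg)
            model.loss_curve = list(f["loss_curve"][()])
            model.val_curve = list(f["val_curve"][()])
        return model


def _batch_from_pairs(
    stack: SectionStack,
    stream,
    n_pairs: int,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    xs: list[np.ndarray] = []
    for _ in range(n_pairs):
        spec = next(stream)
        a, p = extract_pair(stack, spec)
        xs.append(channel_encode(random_policy_apply(a, policy, rng)))
        xs.append(channel_encode(random_policy_apply(p, policy, rng)))
    batch = np.stack(xs)  # [a1, p1, a2, p2, ...]
    idx = np.arange(2 * n_pairs)
    pair_index = idx ^ 1  # swap neighbors
    return batch, pair_index


def train(
    stack: SectionStack,
    mode: SamplingMode | str = SamplingMode.CL3D,
    radius_um: float = 118.0,
    policy: AugmentationPolicy | None = None,
    cfg: EncoderConfig | None = None,
    seed: int = 0,
    steps: int = 300,
    patch_px: int = 48,
    train_sections: list[int] | None = None,
    val_sections: list[int] | None = None,
    val_every: int = 0,
    val_pairs: int = 32,
    log_every: int = 0,
) -> TrainedModel:
    """Train the encoder with spatial-context contrastive learning.

    Pairs are sampled on the fly from ``train_sections`` (all sections by
    default); both members are augmented, channel-encoded and standardized
    before the forward pass.  Raises on loss divergence (NaN).  All
    randomness derives from ``seed``.
    """
    cfg = cfg or EncoderConfig(batch_pairs=64, standardization_batches=16)
    policy = policy or AugmentationPolicy(crop_px=32)
    if policy.crop_px > patch_px:
        raise ValueError("crop must not exceed the anchor patch size")
    mode = SamplingMode(mode)
    if mode in (SamplingMode.CL3D, SamplingMode.NN) and stack.n_sections < 2:
        raise ValueError("cross-section sampling needs at least two sections")

    rng = np.random.default_rng(seed)
    model_rng = np.random.default_rng(rng.integers(2**31))
    aug_rng = np.random.default_rng(rng.integers(2**31))
    stream = pair_stream(
        stack, mode, radius_um, np.random.default_rng(rng.integers(2**31)), patch_px=patch_px, sections=train_sections
    )
    encoder = build_encoder(cfg, rng=model_rng)
    head = ProjectionHead(encoder.feature_dim, cfg.projection_hidden, cfg.projection_out, rng=model_rng)
    standardizer = RunningStandardizer(cfg.input_channels, cfg.standardization_batches)
    opt = nn.Adam(
        encoder.parameters() + head.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )

    val_stream = None
    if val_every and val_sections:
        val_rng_seed = int(rng.integers(2**31))
        val_stream = (val_rng_seed,)

    model = TrainedModel(encoder, head, standardizer, cfg)
    for step in range(steps):
        batch, pair_index = _batch_from_pairs(stack, stream, cfg.batch_pairs, policy, aug_rng)
        standardizer.update(batch)
        x = nn.Tensor(standardizer.apply(batch).astype(np.float32))
        encoder.train()
        head.train()
        h = encoder(x)
        z = nn.l2_normalize_rows(head(h))
        loss = nn.nt_xent_loss(z, pair_index, cfg.temperature)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(f"training diverged at step {step}: loss={value}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_curve.append(value)
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1:5d}  loss {value:.4f}")
        if val_stream is not None and (step + 1) % val_every == 0:
            model.val_curve.append(
                _validation_loss(stack, mode, radius_um, policy, cfg, model, val_sections, val_pairs, patch_px, val_stream[0])
            )
    return model


def _validation_loss(
    stack: SectionStack,
    mode: SamplingMode,
    radius_um: float,
    policy: AugmentationPolicy,
    cfg: EncoderConfig,
    model: TrainedModel,
    sections: list[int],
    n_pairs: int,
    patch_px: int,
    seed: int,
) -> float:
    """Contrastive loss on pairs from held-out sections, fixed seed."""
    rng = np.random.default_rng(seed)
    stream = pair_stream(stack, mode, radius_um, rng, patch_px=patch_px, sections=sections)
    batch, pair_index = _batch_from_pairs(stack, stream, n_pairs, policy, rng)
    model.encoder.eval()
    model.head.eval()
    x = nn.Tensor(model.standardizer.apply(batch).astype(np.float32))
    z = nn.l2_normalize_rows(model.head(model.encoder(x)))
    return float(nn.nt_xent_loss(z, pair_index, cfg.temperature).data)


def infer_feature_map(
    model: TrainedModel,
    maps: ParameterMaps,
    tile_px: int = 128,
    stride_px: int | None = None,
    mask: np.ndarray | None = None,
    section: int = 0,
    batch_size: int = 64,
) -> FeatureMap:
    """Sliding-window feature extraction over one section (no augmentation).

    The grid has ``floor((H - tile)/stride) + 1`` rows (likewise columns);
    features are placed at tile centers.  If ``mask`` is given, each tile is
    additionally labeled with the modal mask value of its footprint.
    """
    h, w = maps.shape
    stride = stride_px if stride_px is not None else tile_px // 2
    if tile_px > h or tile_px > w:
        raise ValueError("section smaller than tile")
    hh = (h - tile_px) // stride + 1
    ww = (w - tile_px) // stride + 1
    patches: list[ParameterMaps] = []
    labels = np.zeros((hh, ww), dtype=np.int8) if mask is not None else None
    for iy in range(hh):
        for ix in range(ww):
            sl = (slice(iy * stride, iy * stride + tile_px), slice(ix * stride, ix * stride + tile_px))
            patches.append(
                ParameterMaps(
                    maps.transmittance[sl],
                    maps.direction[sl],
                    maps.retardation[sl],
                    maps.pixel_size_um,
                )
            )
            if labels is not None:
                labels[iy, ix] = np.argmax(np.bincount(mask[sl].ravel().astype(int)))
    feats = model.encode(patches, batch_size=batch_size)
    return FeatureMap(
        features=feats.reshape(hh, ww, -1),
        tile_px=tile_px,
        stride_px=stride,
        section=section,
        pixel_size_um=maps.pixel_size_um,
        tile_labels=labels,
    )
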
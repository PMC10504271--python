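"""The full segmentation model: encoder, latent projections, shared MLP.

Training runs the whole computation through the autodiff graph; inference
extracts the latent grids and decodes through :mod:`faseg.fa_decoder`'s
plain-numpy path (the two are pinned against each other in tests).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import fa_decoder as fa
from . import nn
from .encoder import STRIDES, Encoder, EncoderConfig, FeatureMap, FeaturePyramid
from .imaging import SegmentationMask
from .nn import Tensor
from .nn import autodiff as ad


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    latent_width: int = 32
    pe_bands: int = 8          # L
    pe_omega_base: float = 2.0
    mlp_hidden: tuple[int, ...] = (128, 128)
    num_classes: int = 2
    scale_offsets: bool = False

    @staticmethod
    def preset_tiny() -> "ModelConfig":
        return ModelConfig()

    @staticmethod
    def preset_b5like() -> "ModelConfig":
        return ModelConfig(encoder=EncoderConfig.preset_b5like(),
                           latent_width=64, pe_bands=8,
                           mlp_hidden=(256, 256))

    @staticmethod
    def from_preset(name: str) -> "ModelConfig":
        try:
            return {"tiny": ModelConfig.preset_tiny,
                    "b5like": ModelConfig.preset_b5like}[name]()
        except KeyError:
            raise ValueError(f"unknown model preset {name!r}") from None

    @property
    def pe_spec(self) -> fa.PositionEncodingSpec:
        return fa.PositionEncodingSpec(L=self.pe_bands,
                                       omega_base=self.pe_omega_base)

    @property
    def mlp_input_width(self) -> int:
        return fa.decoder_input_width(self.latent_width, self.pe_spec)


class FANet(nn.Module):
    """Feature-aligned segmentation network."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = Encoder(cfg.encoder, rng=rng)
        # tap channels: stem + stages 2..5
        ch = cfg.encoder.stage_channels
        tap_channels = (ch[0], ch[2], ch[3], ch[4], ch[5])
        self.proj = nn.ModuleList([
            nn.Conv2d(c, cfg.latent_width, 1, bias=True, rng=rng)
            for c in tap_channels
        ])
        self.mlp = nn.MLP(cfg.mlp_input_width, list(cfg.mlp_hidden),
                          cfg.num_classes, rng=rng)

    # -- training path ----------------------------------------------------
    def forward(self, x: Tensor, points: np.ndarray) -> Tensor:
        """Logits at ``points`` for a batch: returns (N * Q, num_classes).

        ``points`` is a (Q, 2) query set shared across the batch; rows of
        the output enumerate queries fastest within each sample.
        """
        points = np.asarray(points, dtype=np.float64)
        taps = self.encoder(x)
        n, q = x.shape[0], points.shape[0]
        spec = self.cfg.pe_spec
        parts: list[Tensor] = []
        for proj, tap in zip(self.proj, taps):
            z = proj(tap)
            h, w = z.shape[2], z.shape[3]
            r, c = fa.nearest_indices(points, h, w)
            zq = ad.moveaxis(ad.take_spatial(z, r, c), 1, 2)  # N x Q x C
            delta = points - fa.level_coords(h, w).reshape(h * w, 2)[r * w + c]
            if self.cfg.scale_offsets:
                delta = delta * np.array([h, w], dtype=np.float64)
            psi = fa.position_encode(delta, spec)
            const = np.concatenate(
                [psi, delta], axis=1).astype(np.float32)[None]  # 1 x Q x ·
            parts.append(zq)
            parts.append(Tensor(np.broadcast_to(const, (n, q, const.shape[2]))))
        feats = ad.concat(parts, axis=-1)
        flat = ad.reshape(feats, (n * q, self.cfg.mlp_input_width))
        return self.mlp(flat)

    # -- inference path ---------------------------------------------------
    def pyramid(self, img: np.ndarray) -> FeaturePyramid:
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                taps = self.encoder(Tensor(np.asarray(img)[None, None]))
        finally:
            self.train(was_training)
        return FeaturePyramid([
            FeatureMap(values=t.data[0], level=i + 1, stride=STRIDES[i])
            for i, t in enumerate(taps)
        ])

    def projection_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p.weight.data[:, :, 0, 0], p.bias.data) for p in self.proj]

    def latent_grids(self, img: np.ndarray) -> list[fa.LatentGrid]:
        return fa.project_to_latents(self.pyramid(img),
                                     self.projection_weights())

    def decoder_mlp(self) -> fa.DecoderMLP:
        return fa.DecoderMLP(
            weights=[(lin.weight.data, lin.bias.data) for lin in self.mlp.layers],
            num_classes=self.cfg.num_classes,
        )

    def predict_logits(self, img: np.ndarray,
                       out_shape: tuple[int, int] | None = None) -> np.ndarray:
        """Decode the continuous field at an arbitrary output grid."""
        img = np.asarray(img)
        if out_shape is None:
            out_shape = img.shape
        return fa.decode_grid(self.latent_grids(img), self.cfg.pe_spec,
                              self.decoder_mlp(), out_shape,
                              self.cfg.scale_offsets)

    def predict(self, img: np.ndarray,
                out_shape: tuple[int, int] | None = None) -> SegmentationMask:
        return fa.predict_mask(self.predict_logits(img, out_shape))


def build_model(cfg: ModelConfig, seed: int = 0) -> FANet:
    """Seeded construction: same seed, bit-identical initial weights."""
    return FANet(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Checkpointing: one .npz holding every array plus the JSON-encoded config.

def _config_to_json(cfg: ModelConfig) -> str:
    d = dataclasses.asdict(cfg)
    return json.dumps(d, sort_keys=True)


def _config_from_json(text: str) -> ModelConfig:
    d = json.loads(text)
    enc = d.pop("encoder")
    for key in ("stage_channels", "stage_depths", "stage_kernels"):
        enc[key] = tuple(enc[key])
    d["mlp_hidden"] = tuple(d["mlp_hidden"])
    return ModelConfig(encoder=EncoderConfig(**enc), **d)


def save_checkpoint(path: str | Path, model: FANet,
                    extra: dict | None = None) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        _config_to_json(model.cfg).encode(), dtype=np.uint8)
    if extra:
        state["__extra__"] = np.frombuffer(
            json.dumps(extra, sort_keys=True).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(path: str | Path) -> tuple[FANet, dict]:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    cfg = _config_from_json(bytes(state.pop("__config__")).decode())
    extra = {}
    if "__extra__" in state:
        extra = json.loads(bytes(state.pop("__extra__")).decode())
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model, extra
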
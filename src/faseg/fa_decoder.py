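"""Feature-alignment decoder: a continuous, coordinate-queried readout.

Instead of upsampling coarse feature maps (which blurs boundaries), each
pyramid level's features are treated as *latent codes* sampled on a regular
grid in the unit square.  A query coordinate x_q is answered by, at every
level i,

* looking up the nearest latent code z_i* and its centre x_i*,
* forming the relative offset  delta_x_i = x_q - x_i*,
* expanding the offset with a sinusoidal position encoding
  psi(u) = (sin(w_1 u), cos(w_1 u), ..., sin(w_L u), cos(w_L u)),

then concatenating (z_i*, psi(delta_x_i), delta_x_i) over the five levels
and passing the vector through a shared MLP that emits class logits.  The
resulting field is defined at every point of [0, 1]^2, so one trained model
decodes at any output resolution.

Conventions (fixed package-wide):

* global frame = unit square, pixel centres at ((r+0.5)/H, (c+0.5)/W),
  rows top->bottom, columns left->right;
* nearest-code ties break toward the smaller row, then smaller column;
* frequencies w_l = omega_base * e^l, l = 1..L (omega_base defaults to 2);
* offsets are expressed in the global frame (optionally rescaled by the
  level's grid size when ``scale_offsets`` is set);
* tied class logits argmax to class 0.

This module is the plain-numpy (float64) inference path; training runs the
same arithmetic through the autodiff graph (see :mod:`faseg.model`, which
tests pin against this path).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoder import FeaturePyramid
from .imaging import SegmentationMask


def level_coords(h: int, w: int) -> np.ndarray:
    """Pixel-centre coordinates of an h x w grid: (h, w, 2) in (0,1)^2."""
    rr = (np.arange(h) + 0.5) / h
    cc = (np.arange(w) + 0.5) / w
    out = np.empty((h, w, 2))
    out[..., 0] = rr[:, None]
    out[..., 1] = cc[None, :]
    return out


@dataclasses.dataclass
class LatentGrid:
    """One level's latent codes with their continuous coordinates."""

    codes: np.ndarray  # C x H x W
    coords: np.ndarray  # H x W x 2
    level: int

    def __post_init__(self):
        if self.codes.ndim != 3:
            raise ValueError("codes must be C x H x W")
        if self.coords.shape != (*self.codes.shape[1:], 2):
            raise ValueError("coords must be H x W x 2 matching codes")


@dataclasses.dataclass
class QueryGrid:
    """Query coordinates, optionally structured as an (H_q, W_q) grid."""

    points: np.ndarray  # N x 2 in [0, 1]^2
    target_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be N x 2")
        if self.points.min() < 0.0 or self.points.max() > 1.0:
            raise ValueError("query coordinates must lie in [0, 1]^2")

    @staticmethod
    def full_grid(shape: tuple[int, int]) -> "QueryGrid":
        h, w = shape
        return QueryGrid(level_coords(h, w).reshape(-1, 2), target_shape=(h, w))


@dataclasses.dataclass
class NearestCode:
    z_star: np.ndarray
    x_star: np.ndarray
    delta: np.ndarray
    index: tuple[int, int]


@dataclasses.dataclass(frozen=True)
class PositionEncodingSpec:
    """Sinusoidal offset encoding with L strictly increasing frequencies."""

    L: int = 8
    omega_base: float = 2.0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def omega(self) -> np.ndarray:
        """w_l = omega_base * e^l for l = 1..L."""
        return self.omega_base * np.exp(np.arange(1, self.L + 1, dtype=np.float64))


@dataclasses.dataclass
class DecoderMLP:
    """Weights of the shared readout f_theta (rectifier hidden layers,
    linear output).  ``weights`` holds (W, b) with W of shape (in, out)."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    num_classes: int

    @property
    def input_width(self) -> int:
        return self.weights[0][0].shape[0]

    @property
    def hidden(self) -> list[int]:
        return [w.shape[1] for w, _ in self.weights[:-1]]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Forward a (..., input_width) array to (..., num_classes)."""
        h = np.asarray(x, dtype=np.float64)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(self.weights):
            h = h @ w + b
            if i < last:
                h = np.maximum(h, 0.0)
        return h


def decoder_input_width(latent_width: int, spec: PositionEncodingSpec,
                        n_levels: int = 5) -> int:
    """Concatenation width: n_levels * (C + 4L + 2)."""
    return n_levels * (latent_width + 4 * spec.L + 2)


# ---------------------------------------------------------------------------
# Latent grids

def project_to_latents(pyr: FeaturePyramid,
                       projections: list[tuple[np.ndarray, np.ndarray]],
                       ) -> list[LatentGrid]:
    """Map each pyramid level to latent codes by a 1x1 convolution.

    ``projections`` holds per-level (weight (C, C_i), bias (C,)) pairs —
    the learned projection extracted from the model.  Coordinates are the
    pixel centres of each level's grid.
    """
    if len(pyr.levels) != 5 or len(projections) != 5:
        raise ValueError("expected a 5-level pyramid with 5 projections")
    grids = []
    for fmap, (w, b) in zip(pyr.levels, projections):
        c_i, h, wd = fmap.values.shape
        if w.shape[1] != c_i:
            raise ValueError(f"projection expects {w.shape[1]} channels, "
                             f"level {fmap.level} has {c_i}")
        codes = np.tensordot(w.astype(np.float64),
                             fmap.values.astype(np.float64), axes=([1], [0]))
        codes += b.astype(np.float64)[:, None, None]
        grids.append(LatentGrid(codes=codes, coords=level_coords(h, wd),
                                level=fmap.level))
    return grids


def identity_projections(pyr: FeaturePyramid) -> list[tuple[np.ndarray, np.ndarray]]:
    """Identity 1x1 projections (codes equal the raw features)."""
    return [(np.eye(f.values.shape[0]), np.zeros(f.values.shape[0]))
            for f in pyr.levels]


# ---------------------------------------------------------------------------
# Nearest-code lookup

def nearest_indices(points: np.ndarray, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the nearest pixel centre for each query.

    Equidistant queries (cell boundaries) resolve to the smaller index,
    implemented as round-half-down of the fractional grid position.
    """
    u = points[:, 0] * h - 0.5
    v = points[:, 1] * w - 0.5
    rows = np.clip(np.ceil(u - 0.5), 0, h - 1).astype(np.int64)
    cols = np.clip(np.ceil(v - 0.5), 0, w - 1).astype(np.int64)
    return rows, cols


def nearest_latent(grid: LatentGrid, x_q: np.ndarray) -> NearestCode:
    """The latent code nearest (Euclidean) to ``x_q``, with its offset.

    Ties break toward the smaller row, then smaller column index.
    """
    x_q = np.asarray(x_q, dtype=np.float64)
    h, w = grid.codes.shape[1:]
    r, c = nearest_indices(x_q[None, :], h, w)
    r, c = int(r[0]), int(c[0])
    x_star = grid.coords[r, c]
    return NearestCode(z_star=grid.codes[:, r, c], x_star=x_star,
                       delta=x_q - x_star, index=(r, c))


# ---------------------------------------------------------------------------
# Position encoding

def position_encode(delta: np.ndarray, spec: PositionEncodingSpec) -> np.ndarray:
    """psi applied per offset component; output (..., 4L) in [-1, 1].

    Layout: for each component u of (row, col) order, the 2L values
    (sin(w_1 u), cos(w_1 u), ..., sin(w_L u), cos(w_L u)).
    """
    delta = np.asarray(delta, dtype=np.float64)
    omega = spec.omega
    ang = delta[..., :, None] * omega  # (..., 2, L)
    enc = np.empty((*ang.shape[:-1], 2 * spec.L))
    enc[..., 0::2] = np.sin(ang)
    enc[..., 1::2] = np.cos(ang)
    return enc.reshape(*delta.shape[:-1], 4 * spec.L)


# ---------------------------------------------------------------------------
# Decoding

def _gather_features(points: np.ndarray, grids: list[LatentGrid],
                     spec: PositionEncodingSpec,
                     scale_offsets: bool = False) -> np.ndarray:
    """Concatenated (z_i*, psi(dx_i), dx_i) over levels; (N, D)."""
    parts = []
    for grid in grids:
        h, w = grid.codes.shape[1:]
        r, c = nearest_indices(points, h, w)
        z = grid.codes[:, r, c].T  # N x C
        delta = points - grid.coords[r, c]
        if scale_offsets:
            delta = delta * np.array([h, w], dtype=np.float64)
        parts.extend([z, position_encode(delta, spec), delta])
    return np.concatenate(parts, axis=1)


def decode_point(x_q: np.ndarray, grids: list[LatentGrid],
                 spec: PositionEncodingSpec, mlp: DecoderMLP,
                 scale_offsets: bool = False) -> np.ndarray:
    """Class logits of the continuous field at a single query point."""
    feats = _gather_features(np.asarray(x_q, dtype=np.float64)[None, :],
                             grids, spec, scale_offsets)
    if feats.shape[1] != mlp.input_width:
        raise ValueError(f"MLP expects input width {mlp.input_width}, "
                         f"features have {feats.shape[1]}")
    return mlp.apply(feats)[0]


_DECODE_CHUNK = 65536  # queries per block: bounds the float64 feature matrix


def decode_points(points: np.ndarray, grids: list[LatentGrid],
                  spec: PositionEncodingSpec, mlp: DecoderMLP,
                  scale_offsets: bool = False) -> np.ndarray:
    """Vectorised logits for an (N, 2) query set (block-wise over queries)."""
    points = np.asarray(points, dtype=np.float64)
    out = np.empty((points.shape[0], mlp.weights[-1][0].shape[1]))
    for start in range(0, points.shape[0], _DECODE_CHUNK):
        block = points[start:start + _DECODE_CHUNK]
        feats = _gather_features(block, grids, spec, scale_offsets)
        if feats.shape[1] != mlp.input_width:
            raise ValueError(f"MLP expects input width {mlp.input_width}, "
                             f"features have {feats.shape[1]}")
        out[start:start + _DECODE_CHUNK] = mlp.apply(feats)
    return out


def decode_grid(grids: list[LatentGrid], spec: PositionEncodingSpec,
                mlp: DecoderMLP, target_shape: tuple[int, int],
                scale_offsets: bool = False) -> np.ndarray:
    """Logits at every pixel centre of ``target_shape``: (H_q, W_q, K).

    Any target resolution is valid from the same latent grids — the field
    is continuous, so no retraining or resampling is involved.
    """
    h, w = target_shape
    if h < 1 or w < 1:
        raise ValueError("target shape sides must be >= 1")
    pts = QueryGrid.full_grid((h, w)).points
    return decode_points(pts, grids, spec, mlp, scale_offsets).reshape(h, w, -1)


def predict_mask(logits: np.ndarray) -> SegmentationMask:
    """Per-pixel argmax over the trailing class axis (ties -> class 0)."""
    labels = np.argmax(logits, axis=-1)
    return SegmentationMask((labels == 1).astype(np.uint8))
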
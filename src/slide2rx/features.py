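"""Per-tile feature extraction and autoencoder compression.

Each retained 224x224 tile is represented by a 2,048-dimensional feature
vector produced by a pluggable backend, then compressed to 512 dimensions by
an autoencoder with a single 512-neuron bottleneck (trained with Adam on MSE
reconstruction loss).  Compression removes noise and the pervasive
always-zero coordinates of raw backend features, and cuts the regressors'
input width by 4x.

Backends are registered in ``FEATURE_BACKENDS``.  The built-in
``deterministic-texture`` backend summarises a tile by hand-crafted texture
statistics — channel moments, Sobel-gradient histograms, oriented spectral
energies and gray-level co-occurrence differences — expanded to 2,048
dimensions through a fixed seeded rectified random projection.  It is fully
deterministic given the tile bytes, needs no downloaded weights, and makes
procedurally generated texture cohorts learnable at desk scale.  A
convolutional backend (e.g. an ImageNet-pretrained residual network) can be
registered under its own tag by callers that have one available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from ._nn import SeededMLP
from .slide_tiler import TileSet, _to_grayscale

__all__ = [
    "FeatureMatrix",
    "AutoencoderModel",
    "FEATURE_BACKENDS",
    "texture_features",
    "extract_features",
    "train_autoencoder",
    "compress_features",
]

RAW_FEATURE_DIM = 2048
COMPRESSED_DIM = 512

_PROJECTION_SEED = 20481  # fixed: the projection is part of the backend definition


@dataclass
class FeatureMatrix:
    tile_ids: list[str]
    features: np.ndarray  # tiles x d
    backend_tag: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D tiles x d matrix")
        if len(self.tile_ids) != self.features.shape[0]:
            raise ValueError("tile_ids length must match feature rows")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")

    @property
    def d(self) -> int:
        return self.features.shape[1]


def _base_texture_stats(pixels: np.ndarray) -> np.ndarray:
    """Hand-crafted texture summary of one RGB tile (order ~200 features)."""
    p = np.asarray(pixels, dtype=float)
    gray = _to_grayscale(p)
    feats: list[np.ndarray] = []

    feats.append(p.reshape(-1, 3).mean(axis=0))          # channel means
    feats.append(p.reshape(-1, 3).std(axis=0))           # channel stds
    feats.append(np.array([gray.mean(), gray.std()]))

    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    hist, _ = np.histogram(mag, bins=16, range=(0.0, 800.0))
    feats.append(hist / mag.size)
    feats.append(np.array([mag.mean(), mag.std()]))

    # oriented spectral energy: radial x angular bins of the magnitude
    # spectrum of the mean-removed grayscale image
    f = np.fft.fftshift(np.abs(np.fft.fft2(gray - gray.mean())))
    h, w = f.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr = np.hypot(yy - cy, xx - cx) / (min(h, w) / 2.0)
    th = np.mod(np.arctan2(yy - cy, xx - cx), np.pi)
    n_rad, n_ang = 16, 8
    r_idx = np.clip((rr * n_rad).astype(int), 0, n_rad - 1)
    a_idx = np.clip((th / np.pi * n_ang).astype(int), 0, n_ang - 1)
    spect = np.zeros((n_rad, n_ang))
    np.add.at(spect, (r_idx, a_idx), f)
    feats.append(np.log1p(spect / f.size).ravel())

    # gray-level difference histograms at small offsets (co-occurrence summary)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (0, 4), (4, 0)):
        diff = gray[dy:, dx:] - gray[: gray.shape[0] - dy, : gray.shape[1] - dx] if (dy or dx) else gray
        dh, _ = np.histogram(np.abs(diff), bins=8, range=(0.0, 128.0))
        feats.append(dh / diff.size)

    return np.concatenate(feats)


_PROJECTION_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _projection(d_base: int) -> tuple[np.ndarray, np.ndarray]:
    if d_base not in _PROJECTION_CACHE:
        rng = np.random.default_rng(_PROJECTION_SEED)
        w = rng.normal(0.0, 1.0 / np.sqrt(d_base), size=(d_base, RAW_FEATURE_DIM))
        b = rng.normal(0.0, 1.0, size=RAW_FEATURE_DIM)
        _PROJECTION_CACHE[d_base] = (w, b)
    return _PROJECTION_CACHE[d_base]


def texture_features(pixels: np.ndarray) -> np.ndarray:
    """2,048-d deterministic texture vector for one resized RGB tile.

    Base statistics are variance-stabilised with arcsinh and expanded by a
    fixed rectified random projection; the rectification leaves a sizeable
    fraction of coordinates at exactly zero, mimicking the sparsity of
    pretrained convolutional features.
    """
    base = np.arcsinh(_base_texture_stats(pixels))
    w, b = _projection(base.size)
    return np.maximum(base @ w + b, 0.0)


FEATURE_BACKENDS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "deterministic-texture": texture_features,
    "texture": texture_features,
}


def extract_features(tiles: TileSet, backend: str = "deterministic-texture") -> FeatureMatrix:
    """One 2,048-vector per retained tile, in manifest order."""
    if backend not in FEATURE_BACKENDS:
        raise ValueError(f"unknown feature backend {backend!r}; registered: {sorted(FEATURE_BACKENDS)}")
    fn = FEATURE_BACKENDS[backend]
    rows, ids = [], []
    for t in tiles.retained_tiles:
        if t.pixels.shape[0] != tiles.resize_edge or t.pixels.shape[1] != tiles.resize_edge:
            raise ValueError(
                f"tile ({t.grid_row},{t.grid_col}) of slide {tiles.slide_id} is not "
                f"resized to {tiles.resize_edge}x{tiles.resize_edge}"
            )
        rows.append(fn(t.pixels))
        ids.append(f"{tiles.slide_id}:{t.grid_row}:{t.grid_col}")
    feats = np.asarray(rows, dtype=float) if rows else np.empty((0, RAW_FEATURE_DIM))
    if feats.shape[1] != RAW_FEATURE_DIM:
        raise ValueError(f"backend produced d={feats.shape[1]}, expected {RAW_FEATURE_DIM}")
    return FeatureMatrix(ids, feats, backend_tag=backend)


@dataclass
class AutoencoderModel:
    """2048 -> 512 -> 2048 bottleneck autoencoder.

    Single ReLU hidden bottleneck, linear output, dropout 0.2, trained with
    Adam on MSE; the encoder is the first layer's post-ReLU activations.
    Inputs are centred/scaled with training-set per-coordinate statistics
    (raw backend features carry a large shared offset that would otherwise
    dominate the reconstruction loss and leave most bottleneck units dead);
    reconstructions are mapped back to the raw feature scale.
    """

    net: SeededMLP = field(repr=False)
    x_center: np.ndarray = field(default=None, repr=False)
    x_scale: np.ndarray = field(default=None, repr=False)
    fitted: bool = False
    training_tag: str = ""

    def encode(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("autoencoder is not fitted")
        return self.net.hidden((np.asarray(x, dtype=float) - self.x_center) / self.x_scale, layer=1)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("autoencoder is not fitted")
        z = self.net.predict((np.asarray(x, dtype=float) - self.x_center) / self.x_scale)
        return z * self.x_scale + self.x_center


def train_autoencoder(features: FeatureMatrix, config) -> AutoencoderModel:
    """Fit the compression autoencoder on raw backend features.

    ``config`` is a :class:`~slide2rx.regressor.TrainingConfig`; a seeded
    10% split of the rows serves as the early-stopping validation set
    (patience on validation reconstruction MSE).
    """
    x = features.features
    if x.shape[1] != RAW_FEATURE_DIM:
        raise ValueError(f"autoencoder expects d={RAW_FEATURE_DIM}, got {x.shape[1]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 feature rows")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(x.shape[0])
    n_val = max(1, x.shape[0] // 10)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        tr_idx = val_idx
    xc = x[tr_idx].mean(axis=0)
    xs = x[tr_idx].std(axis=0)
    xs = np.where(xs < 1e-8, 1.0, xs)
    xz = (x - xc) / xs
    net = SeededMLP(
        (RAW_FEATURE_DIM, COMPRESSED_DIM, RAW_FEATURE_DIM),
        out_activation="linear",
        dropout=config.dropout,
        seed=config.seed,
    )
    net.fit(
        xz[tr_idx], xz[tr_idx], xz[val_idx], xz[val_idx],
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
    )
    return AutoencoderModel(
        net=net, x_center=xc, x_scale=xs, fitted=True,
        training_tag=f"ae-seed{config.seed}",
    )


def compress_features(features: FeatureMatrix, model: AutoencoderModel) -> FeatureMatrix:
    """Encode a raw 2,048-d feature matrix to the 512-d bottleneck."""
    if not model.fitted:
        raise ValueError("autoencoder is not fitted")
    z = model.encode(features.features)
    return FeatureMatrix(
        list(features.tile_ids), z,
        backend_tag=f"{features.backend_tag}+{model.training_tag}",
    )
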
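"""Slide tiling: partition a whole-slide image into non-overlapping tiles,
keep the ones that contain tissue, colour-normalize and resize them.

Tissue detection follows the classic Sobel-gradient rule: a tile is discarded
when more than half of its pixels have a weighted gradient magnitude below a
threshold (default 15, sensible range 10-20 depending on image quality).
"Weighted" gradient means the magnitude is computed on the luminance-weighted
grayscale conversion 0.299 R + 0.587 G + 0.114 B.  Retained tiles are
colour-normalized (Reinhard mean/variance matching in Lab space by default,
Macenko stain-vector normalization optional, identity for synthetic fixtures)
and bilinearly resized from 512x512 to the 224x224 input expected by the
feature extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "SlideImage",
    "Tile",
    "TileSet",
    "compute_gradient_map",
    "tile_slide",
    "filter_tiles",
    "normalize_color",
    "resize_tiles",
    "reinhard_stats",
    "process_slide",
]

DEFAULT_TILE_EDGE = 512
DEFAULT_GRADIENT_THRESHOLD = 15.0
DEFAULT_RESIZE_EDGE = 224

#: Lab-space (mean, std) per channel of an idealized H&E-stained tile; used
#: when no explicit Reinhard reference is supplied.
DEFAULT_REINHARD_REFERENCE = (
    np.array([65.0, 25.0, -8.0]),
    np.array([14.0, 9.0, 6.0]),
)


@dataclass
class SlideImage:
    """An RGB slide (or slide region) at nominal 20x magnification."""

    slide_id: str
    patient_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    magnification: float = 20.0
    preparation: str = "synthetic"  # FFPE | FF | synthetic

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be H x W x 3 (RGB)")


@dataclass
class Tile:
    slide_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray
    frac_low_gradient: float = float("nan")
    retained: bool = True


@dataclass
class TileSet:
    slide_id: str
    patient_id: str
    tiles: list[Tile] = field(default_factory=list)
    tile_edge: int = DEFAULT_TILE_EDGE
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD
    resize_edge: int = DEFAULT_RESIZE_EDGE

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def retained_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.retained]


def _to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale: 0.299 R + 0.587 G + 0.114 B."""
    p = np.asarray(pixels, dtype=float)
    return p[..., 0] * 0.299 + p[..., 1] * 0.587 + p[..., 2] * 0.114


def compute_gradient_map(image: SlideImage | np.ndarray) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude on the grayscale conversion.

    Magnitude is ``sqrt(gx^2 + gy^2)`` from the standard 3x3 Sobel kernels,
    with edge replication at the border.
    """
    pixels = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 Sobel kernel")
    gray = _to_grayscale(pixels) if pixels.ndim == 3 else pixels.astype(float)
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def tile_slide(image: SlideImage, tile_edge: int = DEFAULT_TILE_EDGE) -> TileSet:
    """Partition a slide into non-overlapping ``tile_edge`` square tiles.

    The grid starts at the origin; right/bottom remainder pixels are
    discarded, so exactly ``floor(H/edge) * floor(W/edge)`` tiles result.
    """
    if tile_edge < 1:
        raise ValueError("tile_edge must be >= 1")
    h, w = image.pixels.shape[:2]
    n_rows, n_cols = h // tile_edge, w // tile_edge
    ts = TileSet(slide_id=image.slide_id, patient_id=image.patient_id, tile_edge=tile_edge)
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "slide %s (%dx%d) smaller than tile edge %d; empty tile set",
            image.slide_id, h, w, tile_edge,
        )
        return ts
    for r in range(n_rows):
        for c in range(n_cols):
            block = image.pixels[
                r * tile_edge : (r + 1) * tile_edge,
                c * tile_edge : (c + 1) * tile_edge,
            ]
            ts.tiles.append(Tile(image.slide_id, r, c, block.copy()))
    return ts


def filter_tiles(
    tiles: TileSet,
    gradient_map: np.ndarray,
    threshold: float = DEFAULT_GRADIENT_THRESHOLD,
) -> TileSet:
    """Flag tiles as retained/removed by the low-gradient-fraction rule.

    A tile is removed iff strictly more than half of its pixels have
    gradient magnitude below ``threshold`` (a tile with exactly half is
    retained).  ``frac_low_gradient`` is recorded on every tile.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    edge = tiles.tile_edge
    for t in tiles.tiles:
        r0, c0 = t.grid_row * edge, t.grid_col * edge
        if r0 + edge > gradient_map.shape[0] or c0 + edge > gradient_map.shape[1]:
            raise ValueError("gradient map not aligned with tile pixel blocks")
        block = gradient_map[r0 : r0 + edge, c0 : c0 + edge]
        frac = float(np.mean(block < threshold))
        t.frac_low_gradient = frac
        t.retained = frac <= 0.5
    tiles.gradient_threshold = float(threshold)
    return tiles


def reinhard_stats(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, std) of an RGB tile in Lab space."""
    lab = skcolor.rgb2lab(np.asarray(pixels, dtype=np.uint8))
    return lab.reshape(-1, 3).mean(axis=0), lab.reshape(-1, 3).std(axis=0)


def _reinhard_normalize(pixels: np.ndarray, ref_mean: np.ndarray, ref_std: np.ndarray) -> np.ndarray:
    lab = skcolor.rgb2lab(np.asarray(pixels, dtype=np.uint8))
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std < 1e-8):
        logger.warning("degenerate tile (zero colour variance); returned unchanged")
        return np.asarray(pixels, dtype=np.uint8).copy()
    lab = (lab - mean) / std * ref_std + ref_mean
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def _macenko_normalize(pixels: np.ndarray, ref_stains: np.ndarray | None = None) -> np.ndarray:
    """Macenko stain-vector normalization (deterministic, desk-scale variant).

    Optical densities are decomposed with an SVD; the two extreme stain
    directions (robust angular percentiles) are mapped onto reference
    hematoxylin/eosin vectors and concentrations re-scaled by their 99th
    percentiles.
    """
    if ref_stains is None:
        ref_stains = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]]).T
    p = np.asarray(pixels, dtype=float)
    od = -np.log10(np.clip(p, 1, 255) / 255.0).reshape(-1, 3)
    mask = od.sum(axis=1) > 0.05
    if mask.sum() < 10:
        logger.warning("degenerate tile for Macenko normalization; returned unchanged")
        return np.asarray(pixels, dtype=np.uint8).copy()
    odf = od[mask]
    _, _, vt = np.linalg.svd(odf - odf.mean(axis=0), full_matrices=False)
    plane = vt[:2].T
    proj = odf @ plane
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    v1 = plane @ np.array([np.cos(np.percentile(angles, 1)), np.sin(np.percentile(angles, 1))])
    v2 = plane @ np.array([np.cos(np.percentile(angles, 99)), np.sin(np.percentile(angles, 99))])
    stains = np.stack([v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)], axis=1)
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    scale = np.percentile(np.abs(conc), 99, axis=1)
    scale[scale < 1e-8] = 1.0
    conc = conc / scale[:, None]
    od_norm = (ref_stains * np.array([1.0, 1.0])) @ conc
    rgb = 255.0 * np.power(10.0, -od_norm.T).reshape(p.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def normalize_color(
    tiles: TileSet,
    reference_stats: tuple[np.ndarray, np.ndarray] | None = None,
    method: str = "reinhard",
) -> TileSet:
    """Colour-normalize the retained tiles of a tile set.

    ``method`` is one of ``reinhard`` (Lab mean/variance matching against
    ``reference_stats`` or the bundled H&E reference), ``macenko``
    (stain-vector normalization) or ``identity`` (no-op, for synthetic
    fixtures).  Deterministic given tile and reference.
    """
    if method == "identity":
        return tiles
    if method == "reinhard":
        ref_mean, ref_std = (
            reference_stats if reference_stats is not None else DEFAULT_REINHARD_REFERENCE
        )
        for t in tiles.tiles:
            if t.retained:
                t.pixels = _reinhard_normalize(t.pixels, np.asarray(ref_mean), np.asarray(ref_std))
        return tiles
    if method == "macenko":
        for t in tiles.tiles:
            if t.retained:
                t.pixels = _macenko_normalize(t.pixels)
        return tiles
    raise ValueError(f"unknown colour normalization method: {method!r}")


def resize_tiles(tiles: TileSet, edge: int = DEFAULT_RESIZE_EDGE) -> TileSet:
    """Bilinearly resize every retained tile to ``edge`` x ``edge``."""
    for t in tiles.tiles:
        if not t.retained:
            continue
        if t.pixels.shape[0] != t.pixels.shape[1]:
            raise ValueError("tiles must be square before resizing")
        if t.pixels.shape[0] == edge:
            continue
        out = _sk_resize(
            t.pixels.astype(float), (edge, edge, 3),
            order=1, anti_aliasing=False, preserve_range=True,
        )
        t.pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    tiles.resize_edge = edge
    return tiles


def process_slide(
    image: SlideImage,
    tile_edge: int = DEFAULT_TILE_EDGE,
    threshold: float = DEFAULT_GRADIENT_THRESHOLD,
    resize_edge: int = DEFAULT_RESIZE_EDGE,
    color_norm: str = "identity",
    reference_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> TileSet:
    """Full tiler: tile, gradient-filter, colour-normalize, resize."""
    ts = tile_slide(image, tile_edge)
    if len(ts) == 0:
        return ts
    grad = compute_gradient_map(image)
    ts = filter_tiles(ts, grad, threshold)
    ts = normalize_color(ts, reference_stats, method=color_norm)
    ts = resize_tiles(ts, resize_edge)
    return ts


def rotate_slide(image: SlideImage, quarter_turns: int) -> SlideImage:
    """Rotate a slide by 90-degree increments (data augmentation)."""
    return replace(image, pixels=np.rot90(image.pixels, k=quarter_turns % 4).copy())
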
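"""Trichrome histology quantification.

Masson's trichrome renders collagen in blue tones, preserved neural tissue
in red-purple (hematoxylin) tones, a reduced-graphene-oxide scaffold in
near-black tones, and the empty substrate in near-white tones.  The
pipeline here reduces an RGB section to a small colour palette by k-means,
maps each palette colour to a tissue class, quantifies class areas and the
blue/purple (collagen/tissue) ratio, scores per-pixel collagen compactness
by neighbourhood-summed stain intensity, and measures the spatial
homogeneity of structure colonization with a distributional homogeneity
index (DHI).

Numerical contract for compactness
----------------------------------
Stain intensity is the complement of the luminance of a collagen pixel,
``(255 - gray) / 255`` with ``gray = 0.299 R + 0.587 G + 0.114 B``.
Internally intensities live on an exact 1/255000 grid (per-mil integer
luminance weights 299/587/114), and neighbourhood sums are accumulated in
64-bit integers with a single float division at the end.  Sums are
therefore exact and independent of summation order, so the operation can
be checked bit-for-bit against a brute-force double loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import ParameterError, RuleError

#: fixed-point scale for stain intensities (per-mil luminance weights x 255)
INTENSITY_SCALE = 255_000
_LUMA_WEIGHTS = np.array([299, 587, 114], dtype=np.int64)


class TissueClass(IntEnum):
    """Pixel classes of a segmented trichrome section."""

    BACKGROUND = 0
    COLLAGEN = 1
    TISSUE = 2
    SCAFFOLD = 3


# --------------------------------------------------------------------------
# colour clustering
# --------------------------------------------------------------------------

@dataclass
class ColorClusterModel:
    """k-means colour reduction of an RGB image.

    Every pixel's label is the index of its nearest centroid in Euclidean
    RGB distance; ties break toward the lowest cluster index.
    """

    k: int
    centroids: np.ndarray        # (k, 3) float RGB
    labels: np.ndarray           # (H, W) int
    seed: int


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ParameterError("expected an H x W x 3 RGB image")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ParameterError("empty image")
    return image


def cluster_colors(image: np.ndarray, k: int = 16, seed: int = 0) -> ColorClusterModel:
    """Reduce an RGB image to ``k`` representative colours with k-means.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
    k : number of colour clusters (the study used 16).
    seed : random state for centroid initialisation; fixed seed gives
        identical labels.
    """
    image = _as_rgb(image)
    if k < 2:
        raise ParameterError("k must be >= 2")
    pixels = image.reshape(-1, 3).astype(np.float64)
    # cluster on the distinct colours, weighted by abundance: identical
    # result in the separable cases and much faster on flat-colour images
    colors, counts = np.unique(pixels, axis=0, return_counts=True)
    if k > colors.shape[0]:
        raise ParameterError(
            f"k={k} exceeds the {colors.shape[0]} distinct colours in the image"
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(colors, sample_weight=counts)
    centroids = km.cluster_centers_
    labels = _nearest_centroid(pixels, centroids).reshape(image.shape[:2])
    return ColorClusterModel(k=k, centroids=centroids, labels=labels, seed=seed)


def _nearest_centroid(pixels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin returns the first minimum -> ties break to lowest index
    d2 = ((pixels[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2) \
        if pixels.shape[0] * centroids.shape[0] <= 2_000_000 else None
    if d2 is None:
        # chunked for large images
        out = np.empty(pixels.shape[0], dtype=np.int64)
        step = max(1, 2_000_000 // centroids.shape[0])
        for i in range(0, pixels.shape[0], step):
            chunk = pixels[i:i + step]
            d = ((chunk[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            out[i:i + step] = np.argmin(d, axis=1)
        return out
    return np.argmin(d2, axis=1)


# --------------------------------------------------------------------------
# centroid -> tissue class rule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassRule:
    """Colour-family rule mapping cluster centroids to tissue classes.

    blue (collagen): B is the dominant channel and B - R >= delta;
    purple (tissue): R and B both exceed G by delta;
    background: all channels >= background_min (near white);
    scaffold: all channels <= scaffold_max (near black) when a scaffold
    is present, otherwise such dark centroids are assigned to tissue and
    flagged for review.  Centroids matching no family fall back to the
    nearest of four prototype colours, with an audit entry.
    """

    delta: float = 20.0
    background_min: float = 220.0
    scaffold_max: float = 60.0
    scaffold_present: bool = True


_PROTOTYPES = {
    TissueClass.BACKGROUND: np.array([255.0, 255.0, 255.0]),
    TissueClass.COLLAGEN: np.array([0.0, 0.0, 255.0]),
    TissueClass.TISSUE: np.array([128.0, 0.0, 128.0]),
    TissueClass.SCAFFOLD: np.array([0.0, 0.0, 0.0]),
}


@dataclass
class PixelClassMap:
    """Per-pixel tissue classes plus the audited centroid->class table."""

    classes: np.ndarray          # (H, W) uint8 of TissueClass values
    class_rule: pd.DataFrame     # per centroid: rgb, class, how, note
    audit: list[str] = field(default_factory=list)


def classify_centroid(rgb: np.ndarray, rule: ClassRule) -> tuple[TissueClass, str, str]:
    """Classify a single centroid colour; returns (class, how, note)."""
    r, g, b = (float(v) for v in rgb)
    if min(r, g, b) >= rule.background_min:
        return TissueClass.BACKGROUND, "rule:background", ""
    if max(r, g, b) <= rule.scaffold_max:
        if rule.scaffold_present:
            return TissueClass.SCAFFOLD, "rule:scaffold", ""
        return TissueClass.TISSUE, "rule:dark-no-scaffold", "flagged for review"
    if b >= r and b >= g and b - r >= rule.delta:
        return TissueClass.COLLAGEN, "rule:blue", ""
    if r - g >= rule.delta and b - g >= rule.delta:
        return TissueClass.TISSUE, "rule:purple", ""
    # fallback: nearest prototype colour
    protos = _PROTOTYPES if rule.scaffold_present else {
        k: v for k, v in _PROTOTYPES.items() if k != TissueClass.SCAFFOLD
    }
    keys = list(protos)
    dists = [np.linalg.norm(np.asarray(rgb, float) - protos[c]) for c in keys]
    cls = keys[int(np.argmin(dists))]
    return cls, "nearest-prototype", "no colour family matched"


def classify_clusters(model: ColorClusterModel, rule: ClassRule | None = None) -> PixelClassMap:
    """Assign each colour cluster, hence each pixel, to a tissue class."""
    rule = rule or ClassRule()
    rows, audit = [], []
    lut = np.empty(model.k, dtype=np.uint8)
    for i, c in enumerate(model.centroids):
        cls, how, note = classify_centroid(c, rule)
        lut[i] = int(cls)
        rows.append({"cluster": i, "r": c[0], "g": c[1], "b": c[2],
                     "class": cls.name, "how": how, "note": note})
        if note:
            audit.append(f"cluster {i} rgb=({c[0]:.0f},{c[1]:.0f},{c[2]:.0f}): {how} ({note})")
    table = pd.DataFrame(rows)
    if table["class"].isna().any():  # defensive; classify_centroid is total
        raise RuleError("rule left a centroid unassigned")
    return PixelClassMap(classes=lut[model.labels], class_rule=table, audit=audit)


# --------------------------------------------------------------------------
# areas and the blue/purple ratio
# --------------------------------------------------------------------------

@dataclass
class AreaReport:
    """Class areas in µm² and the collagen/tissue ('blue/purple') ratio.

    The ratio is computed after excluding background; it is flagged
    undefined when no tissue pixels exist.
    """

    area_per_class: dict[str, float]
    blue_purple_ratio: float
    ratio_defined: bool
    excluded_background: float
    pixel_size: float


def quantify_areas(classmap: PixelClassMap, pixel_size: float) -> AreaReport:
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    px_area = pixel_size ** 2
    areas = {}
    for cls in TissueClass:
        areas[cls.name] = float(np.count_nonzero(classmap.classes == cls) * px_area)
    tissue = areas[TissueClass.TISSUE.name]
    collagen = areas[TissueClass.COLLAGEN.name]
    defined = tissue > 0
    ratio = collagen / tissue if defined else float("nan")
    return AreaReport(
        area_per_class=areas,
        blue_purple_ratio=ratio,
        ratio_defined=defined,
        excluded_background=areas[TissueClass.BACKGROUND.name],
        pixel_size=pixel_size,
    )


# --------------------------------------------------------------------------
# collagen compactness
# --------------------------------------------------------------------------

def blue_intensity(image: np.ndarray, classmap: PixelClassMap) -> np.ndarray:
    """Stain intensity of collagen pixels: (255 - gray)/255, 0 elsewhere.

    The complement is taken because in grey scale 255 is white (no stain).
    Values are quantized on the exact 1/255000 grid (see module docstring).
    """
    image = _as_rgb(image)
    if image.shape[:2] != classmap.classes.shape:
        raise ParameterError("image and class map shapes differ")
    fixed = _intensity_fixed(image, classmap.classes == TissueClass.COLLAGEN)
    return fixed / INTENSITY_SCALE


def _intensity_fixed(image: np.ndarray, collagen_mask: np.ndarray) -> np.ndarray:
    """Integer intensity numerators: 255000 - (299 R + 587 G + 114 B)."""
    gray_fixed = np.tensordot(image.astype(np.int64), _LUMA_WEIGHTS, axes=([2], [0]))
    fixed = INTENSITY_SCALE - gray_fixed
    return np.where(collagen_mask, fixed, 0).astype(np.int64)


@dataclass
class CompactnessMap:
    """Neighbourhood-summed collagen intensity per collagen pixel.

    ``values[p]`` is the pixel's own intensity plus the intensities of all
    pixels in the square (2r+1)² window around it (non-collagen intensities
    are zero); non-collagen pixels carry 0.  Border pixels use the
    in-image part of their window only.
    """

    intensity: np.ndarray        # (H, W) float in [0, 1]
    values: np.ndarray           # (H, W) float, 0 off collagen
    radius: int
    collagen_mask: np.ndarray


def compactness(intensity: np.ndarray, radius: int = 1,
                mask: np.ndarray | None = None) -> CompactnessMap:
    """Sum stain intensity over the (2r+1)² neighbourhood of each pixel.

    Parameters
    ----------
    intensity : float map in [0, 1]; zero on non-collagen pixels.
    radius : half-width of the square window (1 = 8-neighbourhood).
    mask : boolean collagen mask; defaults to ``intensity > 0``.
    """
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 2:
        raise ParameterError("intensity map must be 2-D")
    if mask is None:
        mask = intensity > 0
    elif mask.shape != intensity.shape:
        raise ParameterError("mask and intensity shapes differ")
    q = np.rint(intensity * INTENSITY_SCALE).astype(np.int64)
    q[~mask] = 0
    kernel = np.ones((2 * radius + 1, 2 * radius + 1), dtype=np.int64)
    summed = ndimage.convolve(q, kernel, mode="constant", cval=0)
    values = np.where(mask, summed / INTENSITY_SCALE, 0.0)
    return CompactnessMap(intensity=q / INTENSITY_SCALE, values=values,
                          radius=radius, collagen_mask=np.asarray(mask, bool))


@dataclass
class CompactnessHistogram:
    """Collagen area split into four relative compactness levels.

    Bin edges are quarters of the per-image maximum compactness
    (0-25, 25-50, 50-75, 75-100 %); fractions sum to 1 over collagen area.
    """

    level_areas: np.ndarray      # µm², 4 bins
    level_fractions: np.ndarray  # fractions of collagen area
    edges: np.ndarray            # 5 edges, 0 .. max
    max_compactness: float
    empty: bool


def bin_compactness(cmap: CompactnessMap, pixel_size: float = 1.0) -> CompactnessHistogram:
    values = cmap.values[cmap.collagen_mask]
    if values.size == 0:
        return CompactnessHistogram(
            level_areas=np.zeros(4), level_fractions=np.full(4, np.nan),
            edges=np.zeros(5), max_compactness=0.0, empty=True)
    m = float(values.max())
    if m <= 0:
        counts = np.array([values.size, 0, 0, 0], dtype=float)
    else:
        idx = np.clip(np.floor(values / m * 4).astype(int), 0, 3)
        counts = np.bincount(idx, minlength=4).astype(float)
    areas = counts * pixel_size ** 2
    return CompactnessHistogram(
        level_areas=areas, level_fractions=counts / counts.sum(),
        edges=np.linspace(0.0, m, 5), max_compactness=m, empty=False)


# --------------------------------------------------------------------------
# fluorescence positive area
# --------------------------------------------------------------------------

def positive_area_fraction(channel: np.ndarray, threshold: float) -> float:
    """Percent of pixels at or above an intensity threshold."""
    channel = np.asarray(channel)
    if channel.ndim != 2 or channel.size == 0:
        raise ParameterError("expected a non-empty single-channel image")
    lo, hi = float(channel.min()), float(channel.max())
    if not (lo <= threshold <= hi):
        raise ParameterError(
            f"threshold {threshold} outside the image intensity range [{lo}, {hi}]")
    return 100.0 * float(np.count_nonzero(channel >= threshold)) / channel.size


# --------------------------------------------------------------------------
# distributional homogeneity index
# --------------------------------------------------------------------------

@dataclass
class DHIResult:
    """Scale-aggregated dispersion of local coverage around global coverage.

    For each macropixel size ``s`` the image is tiled into s x s blocks and
    the per-scale heterogeneity is the RMS deviation of block coverage from
    the (trimmed-region) global coverage, divided by that coverage.  The
    index is the mean heterogeneity over scales x 100: 0 for exactly
    uniform coverage, higher for spatially clustered (border-concentrated)
    layouts.
    """

    dhi: float
    macropixel_sizes: list[int]
    per_scale_heterogeneity: np.ndarray
    global_coverage: float
    defined: bool


def default_macropixel_sizes(shape: tuple[int, int]) -> list[int]:
    """Dyadic ladder 4, 8, 16, ... up to a quarter of the short image side.

    Macropixels comparable to single pixels carry no layout information
    for sparse colonization masks, so the ladder starts at 4 px.
    """
    top = max(min(shape) // 4, 4)
    sizes, s = [], 4
    while s <= top and s <= min(shape):
        sizes.append(s)
        s *= 2
    return sizes or [2]


def compute_dhi(mask: np.ndarray,
                macropixel_sizes: Sequence[int] | None = None) -> DHIResult:
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim != 2 or mask.size == 0:
        raise ParameterError("coverage map must be a non-empty 2-D array")
    h, w = mask.shape
    sizes = list(macropixel_sizes) if macropixel_sizes is not None \
        else default_macropixel_sizes(mask.shape)
    for s in sizes:
        if s < 2 or s > min(h, w):
            raise ParameterError(f"macropixel size {s} outside [2, min(H, W)]")
    global_cov = float(mask.mean())
    if global_cov == 0:
        return DHIResult(dhi=float("nan"), macropixel_sizes=sizes,
                         per_scale_heterogeneity=np.full(len(sizes), np.nan),
                         global_coverage=0.0, defined=False)
    het = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        trimmed = mask[: (h // s) * s, : (w // s) * s]
        blocks = trimmed.reshape(h // s, s, w // s, s).mean(axis=(1, 3))
        c = trimmed.mean()
        het[i] = np.sqrt(np.mean((blocks - c) ** 2)) / c if c > 0 else np.nan
    dhi = float(np.nanmean(het) * 100.0)
    return DHIResult(dhi=dhi, macropixel_sizes=sizes, per_scale_heterogeneity=het,
                     global_coverage=global_cov, defined=True)
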
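"""Vessel and neurite morphometry on binary masks.

Quantifies RECA-1-like vessels and βIII-tubulin-like neurites: component
counts (8-connected), per-structure length from the skeleton, vessel
diameter from the medial-axis distance transform, rostro-caudal extent
along a declared image axis, and total length per image.

Length convention: the skeleton path length is the sum of inter-pixel
steps plus one pixel, so that an axis-aligned segment of n pixels
measures exactly n pixels.  Vessel width and centreline length come from
a tube (capsule) model fitted to the component's principal-axis extent
and pixel area, which is free of the orientation bias that raster
distance transforms show on diagonal tubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import ParameterError

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class StructureMask:
    """A binary structure mask with its spatial calibration."""

    mask: np.ndarray
    pixel_size: float = 1.0
    rostro_caudal_axis: str = "columns"   # rows | columns

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if self.mask.dtype != bool:
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError("mask must be binary")
            self.mask = self.mask.astype(bool)
        if self.rostro_caudal_axis not in ("rows", "columns"):
            raise ParameterError("rostro_caudal_axis must be 'rows' or 'columns'")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


@dataclass
class StructureStats:
    """Per-structure morphometrics in µm; ``total_length = sum(lengths)``."""

    n_structures: int
    lengths: np.ndarray
    diameters: np.ndarray         # NaN for neurites
    rostro_caudal_extents: np.ndarray
    total_length: float
    kind: str


def segment_mask(channel: np.ndarray, threshold: float, min_size: int = 10,
                 pixel_size: float = 1.0,
                 rostro_caudal_axis: str = "columns") -> StructureMask:
    """Threshold a fluorescence channel and drop specks below ``min_size`` px."""
    channel = np.asarray(channel)
    if channel.ndim != 2 or channel.size == 0:
        raise ParameterError("expected a non-empty single-channel image")
    if channel.dtype == bool:
        binary = channel.copy()
    else:
        lo, hi = float(channel.min()), float(channel.max())
        if not (lo <= threshold <= hi):
            raise ParameterError(
                f"threshold {threshold} outside intensity range [{lo}, {hi}]")
        binary = channel >= threshold
    if min_size > 1:
        binary = morphology.remove_small_objects(binary, max_size=min_size - 1,
                                                 connectivity=2)
    return StructureMask(mask=binary, pixel_size=pixel_size,
                         rostro_caudal_axis=rostro_caudal_axis)


def _skeleton_steps(skel: np.ndarray) -> tuple[int, int]:
    """Orthogonal/diagonal step counts along an 8-connected skeleton.

    Diagonal steps that can be replaced by two orthogonal steps through a
    common skeleton pixel are skipped to avoid double counting at corners.
    """
    coords = np.transpose(np.nonzero(skel))
    if coords.shape[0] <= 1:
        return 0, 0
    pix = set(map(tuple, coords))
    n_orth = n_diag = 0
    for r, c in pix:
        # forward half-neighbourhood to count each edge once
        if (r, c + 1) in pix:
            n_orth += 1
        if (r + 1, c) in pix:
            n_orth += 1
        if (r + 1, c + 1) in pix and not ((r, c + 1) in pix or (r + 1, c) in pix):
            n_diag += 1
        if (r + 1, c - 1) in pix and not ((r, c - 1) in pix or (r + 1, c) in pix):
            n_diag += 1
    return n_orth, n_diag


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Path length of a skeleton in pixels (excluding the +1 extent term).

    The raster chain of a smooth curve mixes orthogonal and diagonal
    steps; summing 1/sqrt(2) weights overestimates shallow-angle lines by
    up to 8 %.  Instead the step counts are recombined as
    ``hypot(n_orth + n_diag, n_diag)``, which is exact for digital
    straight segments at any orientation and a good estimate for locally
    monotone (smooth) paths.
    """
    n_orth, n_diag = _skeleton_steps(skel)
    return float(np.hypot(n_orth + n_diag, n_diag))


def _tube_geometry(sub: np.ndarray, area: float) -> tuple[float, float]:
    """Width and centreline length of a tubular component.

    The extent E along the principal (PCA) axis and the pixel area A of a
    capsule satisfy A = (E - d) d + (pi/4) d^2, giving
    d = (E - sqrt(E^2 - 4 (1 - pi/4) A)) / (2 (1 - pi/4)) and centreline
    length L = E - d (+1 px pixel-extent convention).
    """
    coords = np.column_stack(np.nonzero(sub)).astype(float)
    if coords.shape[0] < 2:
        return float(coords.shape[0]), float(coords.shape[0])
    coords -= coords.mean(axis=0)
    w, v = np.linalg.eigh(np.cov(coords.T))
    proj = coords @ v[:, np.argmax(w)]
    extent = float(proj.max() - proj.min()) + 1.0
    a = 1.0 - np.pi / 4.0
    disc = extent * extent - 4.0 * a * area
    d = (extent - np.sqrt(max(disc, 0.0))) / (2.0 * a)
    return d, max(extent - d, 1.0)


def measure_structures(smask: StructureMask, kind: str = "neurite") -> StructureStats:
    """Count and measure the disjoint structures of a mask.

    For each 8-connected component: neurite length = skeleton path length
    + 1 px; vessel width and centreline length from the tube model (see
    :func:`_tube_geometry`); rostro-caudal extent = bounding extent along
    the declared axis.  An empty mask yields zero statistics.
    """
    if kind not in ("neurite", "vessel"):
        raise ParameterError(f"unknown structure kind '{kind}'")
    px = smask.pixel_size
    labels = measure.label(smask.mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return StructureStats(0, np.empty(0), np.empty(0), np.empty(0), 0.0, kind)
    lengths, diameters, extents = [], [], []
    axis_col = smask.rostro_caudal_axis == "columns"
    for region in measure.regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox
        # pad so the distance transform and skeleton see the surrounding
        # background even when the component fills its bounding box
        sub = np.pad(labels[rmin:rmax, cmin:cmax] == region.label, 1)
        if kind == "vessel":
            # tube model: a straight tube of centreline length L and
            # width d rasterizes to ~ L*d + (pi/4) d^2 pixels over an
            # extent E = L + d along its axis; solving the quadratic for
            # d from (E, area) is orientation-independent, unlike the
            # raster distance transform which biases diagonal tubes high
            d_px, length_px = _tube_geometry(sub, float(region.area))
            diameters.append(d_px * px)
        else:
            diameters.append(float("nan"))
            skel = morphology.skeletonize(sub)
            length_px = _skeleton_length_px(skel) + 1.0
        lengths.append(length_px * px)
        extent_px = (cmax - cmin) if axis_col else (rmax - rmin)
        extents.append(extent_px * px)
    lengths = np.asarray(lengths)
    return StructureStats(
        n_structures=n,
        lengths=lengths,
        diameters=np.asarray(diameters),
        rostro_caudal_extents=np.asarray(extents),
        total_length=float(lengths.sum()),
        kind=kind,
    )
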
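"""Synthetic inputs with programmed ground truth for every pipeline stage.

Generators emulate (a) trichrome sections with controllable class-area
fractions and collagen clustering, (b) extracellular recordings with a
stimulus-locked unit of programmed latency, jitter, amplitude and response
probability, spontaneous orthodromic spikes, and collision blocking,
(c) curvilinear neurite / tubular vessel masks with programmed counts,
lengths, diameters and placement (uniform vs border-concentrated), and
(d) landmark scenes with programmed postural angles.

All randomness flows through one seeded ``numpy.random.Generator`` per
call; identical parameters and seed give bit-identical outputs.  Spikes
are waveform templates, not simulated membranes, and structures are drawn
without anti-aliasing so lengths and diameters are exactly countable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import CapacityError, ParameterError
from .ephys import Recording
from .histology import TissueClass

# --------------------------------------------------------------------------
# trichrome images
# --------------------------------------------------------------------------

#: default stain palette (RGB): near-white background, blue collagen,
#: red-purple tissue, near-black scaffold
DEFAULT_PALETTE: dict[TissueClass, tuple[int, int, int]] = {
    TissueClass.BACKGROUND: (245, 245, 248),
    TissueClass.COLLAGEN: (70, 85, 200),
    TissueClass.TISSUE: (165, 70, 150),
    TissueClass.SCAFFOLD: (25, 25, 28),
}


@dataclass(frozen=True)
class SynthHistologyParams:
    """Parameters of a synthetic trichrome section.

    Class-area fractions must sum to 1; realized areas are exact to a
    pixel (largest-remainder rounding).  ``collagen_layout`` places the
    collagen pixels uniformly, in ``cluster_count`` blobs, or in a band
    along the image border.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.65           # µm per pixel
    frac_background: float = 0.40
    frac_collagen: float = 0.30
    frac_tissue: float = 0.25
    frac_scaffold: float = 0.05
    collagen_layout: str = "uniform"   # uniform | clustered | border
    cluster_count: int = 5
    color_noise_sd: float = 6.0
    seed: int = 0

    def fractions(self) -> np.ndarray:
        return np.array([self.frac_background, self.frac_collagen,
                         self.frac_tissue, self.frac_scaffold])

    def validate(self) -> None:
        f = self.fractions()
        if np.any(f < 0) or np.any(f > 1):
            raise ParameterError("class fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ParameterError("class fractions must sum to 1")
        if self.width < 1 or self.height < 1:
            raise ParameterError("image dimensions must be positive")
        if self.collagen_layout not in ("uniform", "clustered", "border"):
            raise ParameterError(f"unknown collagen_layout '{self.collagen_layout}'")
        if self.collagen_layout == "clustered" and self.cluster_count < 1:
            raise ParameterError("cluster_count must be >= 1")


def _class_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n pixels to class fractions."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def gen_trichrome_image(params: SynthHistologyParams
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic trichrome section.

    Returns ``(image, truth_classes)`` where image is (H, W, 3) uint8 and
    truth_classes is the per-pixel :class:`TissueClass` map.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    n = h * w
    counts = _class_counts(params.fractions(), n)
    classes = np.empty(n, dtype=np.uint8)

    rows, cols = np.divmod(np.arange(n), w)
    n_collagen = counts[TissueClass.COLLAGEN]
    if params.collagen_layout == "uniform" or n_collagen == 0:
        order = rng.permutation(n)
        collagen_idx = order[:n_collagen]
        rest_idx = order[n_collagen:]
    else:
        if params.collagen_layout == "clustered":
            centers = np.column_stack([rng.integers(0, h, params.cluster_count),
                                       rng.integers(0, w, params.cluster_count)])
            d2 = np.full(n, np.inf)
            for cy, cx in centers:
                d2 = np.minimum(d2, (rows - cy) ** 2 + (cols - cx) ** 2)
            key = d2 + rng.random(n)          # random tie-break
        else:  # border
            edge = np.minimum(np.minimum(rows, h - 1 - rows),
                              np.minimum(cols, w - 1 - cols)).astype(float)
            key = edge + rng.random(n)
        order = np.argsort(key)
        collagen_idx = order[:n_collagen]
        rest_idx = rng.permutation(order[n_collagen:])
    classes[collagen_idx] = TissueClass.COLLAGEN
    pos = 0
    for cls in (TissueClass.BACKGROUND, TissueClass.TISSUE, TissueClass.SCAFFOLD):
        c = counts[cls]
        classes[rest_idx[pos:pos + c]] = cls
        pos += c
    classes = classes.reshape(h, w)

    palette = np.array([DEFAULT_PALETTE[TissueClass(i)] for i in range(4)],
                       dtype=np.float64)
    image = palette[classes]
    if params.color_noise_sd > 0:
        image = image + rng.normal(0.0, params.color_noise_sd, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, classes


# --------------------------------------------------------------------------
# extracellular recordings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthRecordingParams:
    """Parameters of a synthetic peri-stimulus recording.

    Stimuli come either from explicit ``stim_times`` (seconds) or from
    ``stim_blocks`` -- a sequence of ``(frequency_hz, n_stimuli)`` trains
    separated by 0.5 s gaps.  The stimulus-locked unit fires
    ``unit_latency`` ms after each stimulus with probability
    ``response_prob`` (``high_freq_response_prob`` for trains >= 100 Hz
    when set) and Gaussian latency jitter.  Spontaneous orthodromic spikes
    arrive as a Poisson process at ``spont_rate`` Hz; when
    ``collision_blocking`` is on, a spontaneous spike within
    ``collision_window`` ms before the expected antidromic arrival blocks
    (omits) the antidromic spike, and the trial is flagged collided.
    The stimulus artifact (square transient) defaults off.
    """

    rate: float = 20000.0              # Hz
    noise_sd: float = 5.0              # µV
    stim_times: tuple[float, ...] | None = None
    stim_blocks: tuple[tuple[float, int], ...] = ((5.0, 100),)
    unit_latency: float = 3.0          # ms
    latency_jitter_sd: float = 0.0     # ms
    response_prob: float = 1.0
    high_freq_response_prob: float | None = None
    spike_amplitude: float = 100.0     # µV
    spont_rate: float = 0.0            # Hz
    spont_times: tuple[float, ...] | None = None   # explicit planting (s)
    collision_window: float | None = None   # ms; default unit_latency + 1
    collision_blocking: bool = True
    stim_artifact_amplitude: float = 0.0    # µV
    stim_artifact_width: float = 0.2        # ms
    baseline: float = 1.0              # stimulus-free seconds at the start
    duration: float | None = None      # s; derived from stimuli if None
    seed: int = 0

    def validate(self) -> None:
        if self.unit_latency <= 0:
            raise ParameterError("unit_latency must be positive")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ParameterError("response_prob must lie in [0, 1]")
        if self.high_freq_response_prob is not None \
                and not 0.0 <= self.high_freq_response_prob <= 1.0:
            raise ParameterError("high_freq_response_prob must lie in [0, 1]")
        if self.rate < 8000.0:
            raise ParameterError(
                "sampling rate too low to represent the 1 ms spike template")
        if self.latency_jitter_sd < 0 or self.noise_sd < 0 or self.spont_rate < 0:
            raise ParameterError("noise, jitter and rates must be >= 0")


def spike_template(rate: float, amplitude: float = 1.0) -> tuple[np.ndarray, int]:
    """Biphasic 1 ms waveform (dominant negative lobe) sampled at ``rate``.

    Returns ``(waveform, peak_index)`` where peak_index marks the negative
    peak; spike times refer to this sample.
    """
    n = int(round(1e-3 * rate))
    if n < 8:
        raise ParameterError("sampling rate too low to represent the spike template")
    t = np.arange(n) / n
    w = -np.sin(2 * np.pi * t)
    w[t >= 0.5] *= 0.5              # smaller rebound lobe
    w *= amplitude
    return w, int(np.argmax(-w))


def _stim_schedule(params: SynthRecordingParams) -> tuple[np.ndarray, np.ndarray]:
    if params.stim_times is not None:
        times = np.asarray(params.stim_times, dtype=np.float64)
        return times, np.full(times.size, np.nan)
    times, freqs = [], []
    t = params.baseline
    for f, count in params.stim_blocks:
        if f <= 0 or count < 1:
            raise ParameterError("stim block frequency and count must be positive")
        block = t + np.arange(count) / f
        times.append(block)
        freqs.append(np.full(count, float(f)))
        t = block[-1] + 0.5
    return np.concatenate(times), np.concatenate(freqs)


def gen_recording(params: SynthRecordingParams
                  ) -> tuple[Recording, pd.DataFrame, np.ndarray]:
    """Simulate a recording; returns (recording, truth_table, spont_times).

    The truth table has one row per stimulus with columns stim_time,
    stim_freq, would_respond (the Bernoulli draw), collided, responded
    (spike actually emitted), latency_ms, amplitude.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    stim_times, stim_freqs = _stim_schedule(params)
    if np.any(np.diff(stim_times) <= 0):
        raise ParameterError("stimulus times must be strictly increasing")
    duration = params.duration
    if duration is None:
        duration = (stim_times[-1] if stim_times.size else params.baseline) + 0.05
    elif stim_times.size and stim_times[-1] >= duration:
        raise ParameterError("duration too short for the stimulus schedule")
    n_samples = int(round(duration * params.rate))

    template, peak_idx = spike_template(params.rate, params.spike_amplitude)

    # spontaneous orthodromic spikes: planted explicitly and/or Poisson
    # with 2 ms refractory thinning
    if params.spont_times is not None:
        spont_times = np.sort(np.asarray(params.spont_times, dtype=np.float64))
    elif params.spont_rate > 0:
        n_exp = rng.poisson(params.spont_rate * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_exp))
        spont = []
        last = -np.inf
        for s in cand:
            if s - last >= 2e-3:
                spont.append(s)
                last = s
        spont_times = np.asarray(spont)
    else:
        spont_times = np.empty(0)

    cw_ms = params.collision_window if params.collision_window is not None \
        else params.unit_latency + 1.0

    rows = []
    evoked_times = []
    for t, f in zip(stim_times, stim_freqs):
        p = params.response_prob
        if params.high_freq_response_prob is not None and f >= 100.0:
            p = params.high_freq_response_prob
        would = bool(rng.random() < p)
        lat = params.unit_latency
        if params.latency_jitter_sd > 0:
            lat = max(0.1, lat + rng.normal(0.0, params.latency_jitter_sd))
        arrival = t + lat * 1e-3
        expected_arrival = t + params.unit_latency * 1e-3
        collided = bool(
            would
            and spont_times.size
            and np.any((spont_times >= expected_arrival - cw_ms * 1e-3)
                       & (spont_times < expected_arrival))
        )
        emitted = would and not (collided and params.collision_blocking)
        if emitted:
            evoked_times.append(arrival)
        rows.append({
            "stim_time": t, "stim_freq": f, "would_respond": would,
            "collided": collided and params.collision_blocking,
            "responded": emitted,
            "latency_ms": lat if emitted else float("nan"),
            "amplitude": params.spike_amplitude if emitted else float("nan"),
        })
    truth = pd.DataFrame(rows)

    signal = rng.normal(0.0, params.noise_sd, n_samples) if params.noise_sd > 0 \
        else np.zeros(n_samples)
    for s in np.concatenate([np.asarray(evoked_times), spont_times]):
        i0 = int(round(s * params.rate)) - peak_idx
        j0, j1 = max(i0, 0), min(i0 + template.size, n_samples)
        if j1 > j0:
            signal[j0:j1] += template[j0 - i0:j1 - i0]
    if params.stim_artifact_amplitude > 0:
        wa = max(1, int(round(params.stim_artifact_width * 1e-3 * params.rate)))
        for t in stim_times:
            i0 = int(round(t * params.rate))
            signal[i0:min(i0 + wa, n_samples)] += params.stim_artifact_amplitude

    rec = Recording(signal=signal, rate=params.rate, stim_times=stim_times,
                    stim_freqs=stim_freqs,
                    meta={"unit_latency_ms": params.unit_latency,
                          "collision_window_ms": cw_ms,
                          "seed": params.seed})
    return rec, truth, spont_times


# --------------------------------------------------------------------------
# structure masks (neurites / vessels)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthStructureParams:
    """Parameters of a synthetic neurite/vessel mask.

    Structures are straight segments (1 px wide for neurites; bands of the
    requested diameter for vessels) placed disjointly with >= 2 px
    separation.  ``orientation_bias`` (degrees from the rostro-caudal
    axis) concentrates orientations; ``placement='border'`` confines
    structure centres to a band along the image border.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0            # µm per pixel
    n_structures: int = 10
    kind: str = "neurite"              # neurite | vessel
    length_range: tuple[float, float] = (30.0, 80.0)    # µm
    diameter_range: tuple[float, float] = (6.0, 12.0)   # µm (vessels)
    orientation_bias: float | None = None               # degrees; None = isotropic
    orientation_jitter: float = 15.0                    # degrees
    placement: str = "uniform"         # uniform | border
    border_frac: float = 0.15          # border band width / min(shape)
    rostro_caudal_axis: str = "columns"   # rows | columns
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("neurite", "vessel"):
            raise ParameterError(f"unknown structure kind '{self.kind}'")
        if self.placement not in ("uniform", "border"):
            raise ParameterError(f"unknown placement '{self.placement}'")
        if self.rostro_caudal_axis not in ("rows", "columns"):
            raise ParameterError("rostro_caudal_axis must be 'rows' or 'columns'")
        if self.n_structures < 1:
            raise ParameterError("n_structures must be >= 1")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ParameterError("invalid length_range")
        if lo / self.pixel_size < 2:
            raise ParameterError("structures must span at least 2 pixels")
        dlo, dhi = self.diameter_range
        if self.kind == "vessel" and (dlo <= 0 or dhi < dlo):
            raise ParameterError("invalid diameter_range")


def _stamp_segment(shape, p0, p1, half_width_px) -> np.ndarray:
    """Pixels within half_width_px of segment p0-p1 (hard binary, no AA)."""
    h, w = shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    d = np.asarray(p1, float) - np.asarray(p0, float)
    l2 = float(d @ d)
    if l2 == 0:
        dist2 = (rr - p0[0]) ** 2 + (cc - p0[1]) ** 2
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / l2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (rr - (p0[0] + t * d[0])) ** 2 + (cc - (p0[1] + t * d[1])) ** 2
    if half_width_px <= 0:
        # 1 px line: nearest-pixel rasterization of the segment
        n_steps = int(max(abs(d[0]), abs(d[1]))) + 1
        ts = np.linspace(0.0, 1.0, n_steps)
        r = np.rint(p0[0] + ts * d[0]).astype(int)
        c = np.rint(p0[1] + ts * d[1]).astype(int)
        m = np.zeros(shape, bool)
        m[r, c] = True
        return m
    return dist2 < half_width_px ** 2


def gen_structure_mask(params: SynthStructureParams
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Place disjoint structures; returns (mask, truth_table).

    Truth columns: structure, kind, length_um, diameter_um,
    rc_extent_um, r0, c0, r1, c1.  Length follows the pixel-extent
    convention (Euclidean endpoint distance + 1 px); raises
    :class:`CapacityError` when disjoint placement fails.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    mask = np.zeros((h, w), dtype=bool)
    occupied_dilated = np.zeros((h, w), dtype=bool)
    band = max(2, int(round(params.border_frac * min(h, w))))
    rows = []
    max_tries = 300 * params.n_structures
    placed, tries = 0, 0
    while placed < params.n_structures:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {params.n_structures} disjoint structures "
                f"in a {h}x{w} image after {max_tries} attempts")
        length_um = rng.uniform(*params.length_range)
        span_px = length_um / params.pixel_size - 1.0   # endpoint distance
        if params.orientation_bias is None:
            theta = rng.uniform(0.0, 180.0)
        else:
            theta = params.orientation_bias + rng.normal(0.0, params.orientation_jitter)
        th = np.deg2rad(theta)
        # rostro-caudal axis at theta=0: along columns (x) or rows (y)
        if params.rostro_caudal_axis == "columns":
            direction = np.array([np.sin(th), np.cos(th)])
        else:
            direction = np.array([np.cos(th), np.sin(th)])
        if params.placement == "border":
            side = rng.integers(4)
            if side == 0:
                center = np.array([rng.uniform(0, band), rng.uniform(0, w - 1)])
            elif side == 1:
                center = np.array([rng.uniform(h - 1 - band, h - 1), rng.uniform(0, w - 1)])
            elif side == 2:
                center = np.array([rng.uniform(0, h - 1), rng.uniform(0, band)])
            else:
                center = np.array([rng.uniform(0, h - 1), rng.uniform(w - 1 - band, w - 1)])
        else:
            center = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        p0 = np.rint(center - direction * span_px / 2).astype(int)
        p1 = np.rint(center + direction * span_px / 2).astype(int)
        margin = 1 if params.kind == "neurite" \
            else int(np.ceil(params.diameter_range[1] / params.pixel_size / 2)) + 1
        if (p0.min() < margin or p1.min() < margin
                or p0[0] >= h - margin or p1[0] >= h - margin
                or p0[1] >= w - margin or p1[1] >= w - margin):
            continue
        if np.array_equal(p0, p1):
            continue
        if params.kind == "vessel":
            diameter_um = rng.uniform(*params.diameter_range)
            half_width = diameter_um / params.pixel_size / 2.0
        else:
            diameter_um = float("nan")
            half_width = 0.0
        stamp = _stamp_segment((h, w), p0, p1, half_width)
        if np.any(stamp & occupied_dilated):
            continue
        mask |= stamp
        occupied_dilated |= ndimage.binary_dilation(stamp, iterations=2)
        rr, cc = np.nonzero(stamp)
        coords = cc if params.rostro_caudal_axis == "columns" else rr
        extent_px = int(coords.max() - coords.min() + 1)
        rows.append({
            "structure": placed, "kind": params.kind,
            "length_um": (np.hypot(*(p1 - p0)) + 1.0) * params.pixel_size,
            "diameter_um": diameter_um,
            "rc_extent_um": extent_px * params.pixel_size,
            "r0": p0[0], "c0": p0[1], "r1": p1[0], "c1": p1[1],
        })
        placed += 1
    return mask, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# landmark scenes
# --------------------------------------------------------------------------

@dataclass
class LandmarkScene:
    """Eye/shoulder/hip landmarks (image coordinates, y down) and ground.

    ``true_ctl_angle`` is the interior eye-shoulder-hip angle at the
    shoulder (cervico-thoraco-lumbar); ``true_trunk_angle`` the unsigned
    angle between the shoulder-hip line and the ground direction.
    """

    eye: np.ndarray
    shoulder: np.ndarray
    hip: np.ndarray
    ground_direction: np.ndarray
    true_ctl_angle: float
    true_trunk_angle: float
    frame_id: int = 0


def _rot(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def gen_landmark_scene(ctl_angle: float, trunk_angle: float,
                       scale: float = 100.0, seed: int = 0,
                       frame_id: int = 0) -> LandmarkScene:
    """Construct a scene whose recomputed angles equal the requested ones.

    ``ctl_angle`` must lie in (0, 180], ``trunk_angle`` in [0, 90];
    the shoulder position and segment lengths are randomised, the
    geometry is exact.
    """
    if not 0.0 < ctl_angle <= 180.0:
        raise ParameterError("ctl_angle must lie in (0, 180]")
    if not 0.0 <= trunk_angle <= 90.0:
        raise ParameterError("trunk_angle must lie in [0, 90]")
    rng = np.random.default_rng(seed)
    shoulder = rng.uniform(2 * scale, 4 * scale, size=2)
    ground = np.array([1.0, 0.0])
    # y grows downward: hip sits caudally and lower than the shoulder
    u_hip = np.array([np.cos(np.deg2rad(trunk_angle)),
                      np.sin(np.deg2rad(trunk_angle))])
    # points are (x, y); rotate hip direction by -ctl to place the eye above
    u_eye = _rot(-ctl_angle) @ u_hip
    hip = shoulder + rng.uniform(0.8, 1.2) * scale * u_hip
    eye = shoulder + rng.uniform(0.6, 1.0) * scale * u_eye
    return LandmarkScene(eye=eye, shoulder=shoulder, hip=hip,
                         ground_direction=ground,
                         true_ctl_angle=float(ctl_angle),
                         true_trunk_angle=float(trunk_angle),
                         frame_id=frame_id)


# --------------------------------------------------------------------------
# provenance / file output helpers
# --------------------------------------------------------------------------

def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image as TIFF or PNG depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, image)


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    import imageio.v3 as iio
    return iio.imread(path)


def echo_params(path: str | Path, params) -> None:
    """Echo generator parameters to a YAML file for provenance."""
    d = asdict(params)
    d["__type__"] = type(params).__name__
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)


def scene_to_frame(scene: LandmarkScene) -> pd.DataFrame:
    """Long-format landmark rows (frame, point, x, y) for CSV export."""
    rows = [
        {"frame": scene.frame_id, "point": "eye", "x": scene.eye[0], "y": scene.eye[1]},
        {"frame": scene.frame_id, "point": "shoulder", "x": scene.shoulder[0], "y": scene.shoulder[1]},
        {"frame": scene.frame_id, "point": "hip", "x": scene.hip[0], "y": scene.hip[1]},
        {"frame": scene.frame_id, "point": "ground", "x": scene.ground_direction[0],
         "y": scene.ground_direction[1]},
    ]
    return pd.DataFrame(rows)
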
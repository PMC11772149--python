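"""Antidromic unit identification from peri-stimulus extracellular recordings.

Workflow: band-pass the raw trace (500-5000 Hz, zero phase), detect spikes
against a baseline mean + 3 SD threshold, match spikes to stimuli inside a
response window, build peristimulus time histograms (1 ms bins, normalized
to % of stimuli), and apply the three antidromic identification criteria:

1. constant latency and amplitude of the evoked action potential,
2. reliable following of high-frequency stimulation (> 100 Hz),
3. a positive collision test: a spontaneous orthodromic spike occurring
   just before the expected antidromic arrival blocks the antidromic spike.

A unit is classified antidromic when it meets at least two of the three
criteria; responsive units failing them are classified synaptic; units
with no time-locked response are unresponsive.  Conduction velocity is the
stimulation-to-recording path length divided by response latency
(mm/ms = m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, ParameterError

#: tri-state criterion flag values
INDETERMINATE = None


@dataclass
class Recording:
    """A single-electrode extracellular recording with stimulus events.

    signal is in µV at sampling ``rate`` Hz; ``stim_times`` are stimulus
    onsets in seconds (sorted); ``stim_freqs`` optionally labels each
    stimulus with its train frequency in Hz; ``distances`` maps a
    stimulation site label (e.g. 'rostral'/'caudal') to the path length to
    the recording site in mm.
    """

    signal: np.ndarray
    rate: float
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_freqs: np.ndarray | None = None
    distances: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.stim_times = np.asarray(self.stim_times, dtype=np.float64)
        if np.any(np.diff(self.stim_times) < 0):
            raise ParameterError("stim_times must be sorted")
        duration = self.signal.size / self.rate
        if self.stim_times.size and (self.stim_times[0] < 0
                                     or self.stim_times[-1] >= duration):
            raise ParameterError("stim_times outside the recorded duration")

    @property
    def duration(self) -> float:
        return self.signal.size / self.rate


def bandpass_filter(rec: Recording, low: float = 500.0, high: float = 5000.0,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; preserves spike latencies."""
    if rec.rate <= 2 * high:
        raise ParameterError(
            f"sampling rate {rec.rate} Hz too low for a {high} Hz band edge")
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal)
    return Recording(signal=filtered, rate=rec.rate, stim_times=rec.stim_times,
                     stim_freqs=rec.stim_freqs, distances=dict(rec.distances),
                     meta=dict(rec.meta))


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Detected spike times (s) and absolute peak amplitudes (µV)."""

    spike_times: np.ndarray
    amplitudes: np.ndarray
    threshold_used: float
    baseline_window: tuple[float, float]
    polarity: str


def detect_spikes(rec: Recording, baseline_window: tuple[float, float],
                  polarity: str = "neg", refractory_ms: float = 1.0) -> SpikeTrain:
    """Threshold detection at baseline mean + 3 SD with refractory grouping.

    The threshold is computed on the polarity-adjusted signal (negative
    deflections by extracellular convention) over a baseline window that
    must contain no stimuli.  Contiguous supra-threshold runs closer than
    the refractory period are merged; each group contributes one spike at
    its peak sample.
    """
    if polarity not in ("neg", "pos"):
        raise ParameterError("polarity must be 'neg' or 'pos'")
    t0, t1 = baseline_window
    i0, i1 = int(round(t0 * rec.rate)), int(round(t1 * rec.rate))
    if not (0 <= i0 < i1 <= rec.signal.size):
        raise ParameterError("baseline window outside the recording")
    if np.any((rec.stim_times >= t0) & (rec.stim_times < t1)):
        raise ParameterError("baseline window contains stimuli")
    x = -rec.signal if polarity == "neg" else rec.signal
    base = x[i0:i1]
    if base.size == 0:
        raise ParameterError("empty baseline window")
    threshold = float(base.mean() + 3.0 * base.std())
    refr = max(1, int(round(refractory_ms * 1e-3 * rec.rate)))
    above = np.flatnonzero(x > threshold)
    if above.size == 0:
        return SpikeTrain(np.empty(0), np.empty(0), threshold, baseline_window, polarity)
    # split supra-threshold samples into groups separated by >= refractory
    breaks = np.flatnonzero(np.diff(above) >= refr) + 1
    peaks = []
    for grp in np.split(above, breaks):
        peaks.append(grp[np.argmax(x[grp])])
    peaks = np.asarray(peaks)
    return SpikeTrain(
        spike_times=peaks / rec.rate,
        amplitudes=np.abs(rec.signal[peaks]),
        threshold_used=threshold,
        baseline_window=baseline_window,
        polarity=polarity,
    )


# --------------------------------------------------------------------------
# stimulus-response bookkeeping
# --------------------------------------------------------------------------

def build_response_table(spikes: SpikeTrain, stim_times: np.ndarray,
                         response_window_ms: tuple[float, float] = (0.5, 10.0),
                         stim_freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-stimulus first-spike responses inside the response window.

    Columns: stim_time, stim_freq, responded, latency_ms, amplitude.
    The window start doubles as stimulus-artifact blanking.  Windows are
    truncated at the next stimulus onset so consecutive windows never
    overlap (high-frequency trains shorten the usable window); a window
    start that leaves no room before the next stimulus is an error.
    """
    stim_times = np.asarray(stim_times, dtype=np.float64)
    if stim_times.size == 0:
        raise ParameterError("need at least one stimulus")
    w0, w1 = (v * 1e-3 for v in response_window_ms)
    if not 0 <= w0 < w1:
        raise ParameterError("response window must satisfy 0 <= start < end")
    if stim_times.size > 1 and w0 >= np.min(np.diff(stim_times)):
        raise ParameterError("response window exceeds the inter-stimulus interval")
    times = spikes.spike_times
    rows = []
    for i, t in enumerate(stim_times):
        end = t + w1
        if i + 1 < stim_times.size:
            end = min(end, stim_times[i + 1])
        lo = np.searchsorted(times, t + w0, side="left")
        hi = np.searchsorted(times, end, side="left")
        freq = float(stim_freqs[i]) if stim_freqs is not None else float("nan")
        if hi > lo:
            rows.append({"stim_time": t, "stim_freq": freq, "responded": True,
                         "latency_ms": (times[lo] - t) * 1e3,
                         "amplitude": float(spikes.amplitudes[lo])})
        else:
            rows.append({"stim_time": t, "stim_freq": freq, "responded": False,
                         "latency_ms": float("nan"), "amplitude": float("nan")})
    return pd.DataFrame(rows)


@dataclass
class PSTH:
    """Peristimulus time histogram, 1 ms bins by default.

    ``normalized`` is counts / n_stimuli x 100 (% of stimuli per bin);
    bins are half-open [t, t+bin) with time 0 at stimulus onset.
    """

    edges_ms: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    n_stimuli: int
    bin_ms: float
    window_ms: tuple[float, float]


def psth(spike_times: np.ndarray, stim_times: np.ndarray, bin_ms: float = 1.0,
         window_ms: tuple[float, float] = (-20.0, 50.0)) -> PSTH:
    """Histogram of spike times relative to each stimulus onset."""
    stim_times = np.asarray(stim_times, dtype=np.float64)
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if stim_times.size == 0:
        raise ParameterError("need at least one stimulus")
    w0, w1 = window_ms
    if bin_ms <= 0 or w1 <= w0:
        raise ParameterError("invalid bin width or window")
    n_bins = (w1 - w0) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ParameterError("bins must tile the window exactly")
    n_bins = int(round(n_bins))
    edges = w0 + bin_ms * np.arange(n_bins + 1)
    rel = (spike_times[None, :] - stim_times[:, None]) * 1e3
    rel = rel[(rel >= w0) & (rel < w1)]
    counts, _ = np.histogram(rel, bins=edges)
    return PSTH(edges_ms=edges, counts=counts,
                normalized=counts / stim_times.size * 100.0,
                n_stimuli=stim_times.size, bin_ms=bin_ms, window_ms=(w0, w1))


def psth_from_responses(responses: pd.DataFrame, bin_ms: float = 1.0,
                        window_ms: tuple[float, float] = (0.0, 20.0)) -> PSTH:
    """PSTH of first-response latencies (post-stimulus bins only)."""
    lat = responses.loc[responses["responded"], "latency_ms"].to_numpy()
    stim = responses["stim_time"].to_numpy()
    return psth(stim + lat * 1e-3 if lat.size else np.empty(0),
                stim, bin_ms=bin_ms, window_ms=window_ms) \
        if lat.size else psth(np.empty(0), stim, bin_ms, window_ms)


def spontaneous_spikes(spikes: SpikeTrain, stim_times: np.ndarray,
                       response_window_ms: tuple[float, float] = (0.5, 10.0)
                       ) -> np.ndarray:
    """Spike times outside every post-stimulus response window.

    These are the orthodromic (spontaneous) events used by the collision
    test; stimulus-evoked spikes are excluded by construction.
    """
    stim_times = np.asarray(stim_times, dtype=np.float64)
    times = spikes.spike_times
    if stim_times.size == 0 or times.size == 0:
        return times.copy()
    w0, w1 = (v * 1e-3 for v in response_window_ms)
    evoked = np.zeros(times.size, dtype=bool)
    for t in stim_times:
        lo = np.searchsorted(times, t + w0, side="left")
        hi = np.searchsorted(times, t + w1, side="left")
        evoked[lo:hi] = True
    return times[~evoked]


def efficiency(responses: pd.DataFrame) -> float:
    """Response efficiency: 100 x responded stimuli / total stimuli."""
    n = len(responses)
    if n == 0:
        raise ParameterError("need at least one stimulus")
    return 100.0 * float(responses["responded"].sum()) / n


# --------------------------------------------------------------------------
# the three antidromic criteria
# --------------------------------------------------------------------------

def check_constant_latency(responses: pd.DataFrame, latency_sd_tol: float = 0.3,
                           amplitude_cv_tol: float = 0.3,
                           min_responses: int = 5,
                           outlier_mad_factor: float = 5.0) -> bool | None:
    """Criterion 1: latency SD and amplitude CV below tolerance.

    Trials whose first-window spike deviates from the median latency by
    more than ``max(outlier_mad_factor x MAD, 0.5 ms)`` are excluded
    before computing the SD -- the automated stand-in for the trial-by-
    trial waveform verification that rejects coincident spontaneous
    events.  Returns None (indeterminate) with fewer than
    ``min_responses`` usable responses.
    """
    resp = responses[responses["responded"]]
    if len(resp) < min_responses:
        return INDETERMINATE
    lat = resp["latency_ms"].to_numpy()
    med = float(np.median(lat))
    mad = float(np.median(np.abs(lat - med)))
    keep = np.abs(lat - med) <= max(outlier_mad_factor * mad, 0.5)
    if keep.sum() < min_responses:
        return INDETERMINATE
    lat_sd = float(np.std(lat[keep], ddof=1))
    amp = resp["amplitude"].to_numpy()[keep]
    amp_cv = float(np.std(amp, ddof=1) / np.mean(amp)) if np.mean(amp) > 0 else np.inf
    return bool(lat_sd <= latency_sd_tol and amp_cv <= amplitude_cv_tol)


def check_frequency_following(responses: pd.DataFrame, min_freq: float = 100.0,
                              min_efficiency: float = 90.0) -> bool | None:
    """Criterion 2: response efficiency >= min_efficiency at >= min_freq Hz."""
    if "stim_freq" not in responses or responses["stim_freq"].isna().all():
        return INDETERMINATE
    high = responses[responses["stim_freq"] >= min_freq]
    if len(high) == 0:
        return INDETERMINATE
    return bool(efficiency(high) >= min_efficiency)


def collision_test(responses: pd.DataFrame, spont_spikes: np.ndarray,
                   expected_latency_ms: float,
                   critical_window_ms: float | None = None,
                   latency_tol_ms: float = 0.5,
                   block_fraction: float = 1.0,
                   min_noncollision_eff: float = 50.0) -> bool | None:
    """Criterion 3: spontaneous orthodromic spikes block the antidromic spike.

    A trial is a collision trial when a spontaneous spike falls within the
    critical window before the expected antidromic arrival (default window:
    expected latency + 1 ms refractory).  The test passes when the
    antidromic response (a response at the expected latency +- tolerance)
    is absent in at least ``block_fraction`` of collision trials while
    present in matched non-collision trials.  With no collision trials the
    outcome is indeterminate.
    """
    if expected_latency_ms <= 0:
        raise ParameterError("expected latency must be positive")
    if critical_window_ms is None:
        critical_window_ms = expected_latency_ms + 1.0
    spont = np.sort(np.asarray(spont_spikes, dtype=np.float64))
    stim = responses["stim_time"].to_numpy()
    arrival = stim + expected_latency_ms * 1e-3
    lo = np.searchsorted(spont, arrival - critical_window_ms * 1e-3, side="left")
    hi = np.searchsorted(spont, arrival, side="left")
    is_collision = hi > lo
    antidromic_present = (
        responses["responded"].to_numpy()
        & (np.abs(responses["latency_ms"].to_numpy() - expected_latency_ms)
           <= latency_tol_ms)
    )
    n_coll = int(is_collision.sum())
    if n_coll == 0:
        return INDETERMINATE
    blocked_frac = float(np.mean(~antidromic_present[is_collision]))
    noncoll = antidromic_present[~is_collision]
    noncoll_eff = 100.0 * float(noncoll.mean()) if noncoll.size else 0.0
    return bool(blocked_frac >= block_fraction and noncoll_eff >= min_noncollision_eff)


@dataclass
class AntidromicVerdict:
    """Two-of-three antidromic classification of a recorded unit."""

    constant_latency: bool | None
    follows_high_freq: bool | None
    collision_pass: bool | None
    n_criteria_met: int
    classification: str          # antidromic | synaptic | unresponsive


def is_time_locked(responses: pd.DataFrame, bin_ms: float = 1.0,
                   alpha: float = 1e-3,
                   window_ms: tuple[float, float] = (0.5, 10.0)) -> bool:
    """Whether first-spike latencies concentrate rather than scatter.

    Chance threshold crossings of background noise scatter uniformly over
    the whole response window; genuine evoked responses (even jittered
    synaptic ones) pile into a few PSTH bins.  The latency histogram over
    the response window is tested against uniformity with a chi-square
    test; the unit counts as responsive (time-locked) when uniformity is
    rejected at ``alpha``.  ``window_ms`` should match the window used to
    build the response table.
    """
    from scipy import stats

    lat = responses.loc[responses["responded"], "latency_ms"].to_numpy()
    if lat.size == 0:
        return False
    w0, w1 = window_ms
    hi = max(w1, np.ceil(lat.max() / bin_ms) * bin_ms)
    edges = np.arange(w0, hi + bin_ms / 2, bin_ms)
    if edges.size < 3:              # window narrower than two bins
        return True
    counts, _ = np.histogram(lat, bins=edges)
    p = stats.chisquare(counts).pvalue
    return bool(p < alpha)


def classify_antidromic(constant_latency: bool | None,
                        follows_high_freq: bool | None,
                        collision_pass: bool | None,
                        responses: pd.DataFrame) -> AntidromicVerdict:
    """Antidromic iff >= 2 criteria met; responsive otherwise -> synaptic.

    Indeterminate criteria count as not met.  A unit whose responses are
    not time-locked (no concentrated PSTH bin; see :func:`is_time_locked`)
    is unresponsive -- long/variable-latency units that respond but fail
    the criteria are the synaptic class.
    """
    flags = (constant_latency, follows_high_freq, collision_pass)
    n_met = sum(1 for f in flags if f is True)
    if n_met >= 2:
        cls = "antidromic"
    elif is_time_locked(responses):
        cls = "synaptic"
    else:
        cls = "unresponsive"
    return AntidromicVerdict(*flags, n_criteria_met=n_met, classification=cls)


def caudal_responsiveness(hist: PSTH, n_baseline_bins: int | None = None) -> bool:
    """Respondent when any post-stimulus bin exceeds baseline mean + SD.

    Baseline bins are the pre-stimulus bins of the PSTH (activity previous
    to the stimulation), optionally restricted to the last
    ``n_baseline_bins`` of them.
    """
    pre = hist.counts[hist.edges_ms[:-1] < 0]
    post = hist.counts[hist.edges_ms[:-1] >= 0]
    if pre.size == 0:
        raise ParameterError("PSTH has no pre-stimulus bins")
    if n_baseline_bins is not None:
        if n_baseline_bins < 1 or n_baseline_bins > pre.size:
            raise ParameterError("invalid baseline bin count")
        pre = pre[-n_baseline_bins:]
    threshold = pre.mean() + pre.std()
    return bool(post.size and np.any(post > threshold))


def conduction_velocity(path_length_mm: float, latency_ms: float) -> float:
    """Axonal conduction velocity: path length / latency (mm/ms = m/s)."""
    if path_length_mm <= 0 or latency_ms <= 0:
        raise ParameterError("path length and latency must be positive")
    return path_length_mm / latency_ms


# --------------------------------------------------------------------------
# cohort summaries
# --------------------------------------------------------------------------

def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group unit totals, mean units/animal and % caudal respondents.

    ``table`` has one row per animal with columns: animal, group,
    n_insertions, n_antidromic_units, caudal_respondent.
    """
    required = {"animal", "group", "n_antidromic_units", "caudal_respondent"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ParameterError("empty cohort table")
    if (table["n_antidromic_units"] < 0).any():
        raise ParameterError("unit counts must be >= 0")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        n_animals = len(sub)
        rows.append({
            "group": group,
            "n_animals": n_animals,
            "total_units": int(sub["n_antidromic_units"].sum()),
            "mean_units_per_animal": float(sub["n_antidromic_units"].mean()),
            "sd_units_per_animal": float(sub["n_antidromic_units"].std(ddof=1))
            if n_animals > 1 else float("nan"),
            "pct_caudal_respondent": 100.0 * float(sub["caudal_respondent"].mean()),
            "empty": n_animals == 0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def write_recording_hdf5(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("stim_times", data=rec.stim_times)
        if rec.stim_freqs is not None:
            f.create_dataset("stim_freqs", data=rec.stim_freqs)
        f.attrs["rate"] = rec.rate
        for k, v in rec.distances.items():
            f.attrs[f"distance_{k}_mm"] = v


def read_recording_hdf5(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise DataError(f"recording file not found: {path}")
    with h5py.File(path, "r") as f:
        distances = {k[len("distance_"):-len("_mm")]: float(v)
                     for k, v in f.attrs.items()
                     if k.startswith("distance_") and k.endswith("_mm")}
        return Recording(
            signal=f["signal"][:], rate=float(f.attrs["rate"]),
            stim_times=f["stim_times"][:] if "stim_times" in f else np.empty(0),
            stim_freqs=f["stim_freqs"][:] if "stim_freqs" in f else None,
            distances=distances)


def write_recording_text(prefix: str | Path, rec: Recording) -> None:
    """Delimited-text fallback: <prefix>_signal.tsv and <prefix>_stims.tsv."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_name(prefix.name + "_signal.tsv"), rec.signal,
               header=f"rate_hz={rec.rate}", comments="# ")
    stim = np.column_stack([rec.stim_times,
                            rec.stim_freqs if rec.stim_freqs is not None
                            else np.full_like(rec.stim_times, np.nan)])
    np.savetxt(prefix.with_name(prefix.name + "_stims.tsv"), stim,
               header="stim_time_s\tstim_freq_hz", comments="# ")


def read_recording_text(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    sig_path = prefix.with_name(prefix.name + "_signal.tsv")
    stim_path = prefix.with_name(prefix.name + "_stims.tsv")
    if not sig_path.exists():
        raise DataError(f"recording file not found: {sig_path}")
    with open(sig_path) as f:
        header = f.readline()
    try:
        rate = float(header.split("rate_hz=")[1])
    except (IndexError, ValueError) as exc:
        raise DataError(f"missing rate_hz header in {sig_path}") from exc
    signal = np.loadtxt(sig_path)
    stim_times, stim_freqs = np.empty(0), None
    if stim_path.exists():
        stim = np.atleast_2d(np.loadtxt(stim_path))
        if stim.size:
            stim_times = stim[:, 0]
            if not np.all(np.isnan(stim[:, 1])):
                stim_freqs = stim[:, 1]
    return Recording(signal=signal, rate=rate, stim_times=stim_times,
                     stim_freqs=stim_freqs)
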
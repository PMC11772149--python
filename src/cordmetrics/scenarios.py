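"""Canonical simulate-then-analyze scenarios with known ground truth.

These bundle a generator configuration with the full analysis chain so
that recovery properties (efficiency, latency, three-criteria
classification, collision logic) can be exercised reproducibly from both
the test suite and the reproduction script.

Unit archetypes
---------------
- ``antidromic``: responds 1:1 with near-constant latency, follows the
  200 Hz train, and its spike is blocked by a spontaneous orthodromic
  spike arriving just before the stimulus (collision).
- ``synaptic``: longer, jittered latency, responds only to low-frequency
  stimulation, and fails the collision test (no blocking).
- ``unresponsive``: no stimulus-locked unit at all; with noise, chance
  threshold crossings still populate the response table, which is why
  classification relies on the time-locking test.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import ephys
from .simulate import SynthRecordingParams, gen_recording

#: stimulation protocol: a low-frequency train then a high-frequency train
STIM_BLOCKS = ((5.0, 80), (200.0, 60))
RESPONSE_WINDOW_MS = (0.5, 10.0)
BASELINE_WINDOW = (0.0, 0.9)


def unit_params(kind: str, seed: int, noise_sd: float) -> SynthRecordingParams:
    kw = dict(seed=seed, stim_blocks=STIM_BLOCKS, noise_sd=noise_sd,
              spike_amplitude=100.0)
    if kind == "antidromic":
        return SynthRecordingParams(latency_jitter_sd=0.05, response_prob=1.0,
                                    collision_blocking=True, **kw)
    if kind == "synaptic":
        return SynthRecordingParams(unit_latency=7.0, latency_jitter_sd=0.8,
                                    response_prob=0.6,
                                    high_freq_response_prob=0.05,
                                    collision_blocking=False, **kw)
    if kind == "unresponsive":
        return SynthRecordingParams(response_prob=0.0, **kw)
    raise ValueError(f"unknown unit kind '{kind}'")


def _with_colliders(params: SynthRecordingParams,
                    every: int = 6) -> SynthRecordingParams:
    """Plant spontaneous spikes 0.5 ms before every n-th low-freq stimulus."""
    rec0, _, _ = gen_recording(replace(params, spont_times=None))
    low = rec0.stim_times[rec0.stim_freqs == STIM_BLOCKS[0][0]]
    colliders = tuple((low[::every] - 0.5e-3).tolist())
    return replace(params, spont_times=colliders)


def analyze_recording(rec, noise_sd: float):
    """Standard analysis chain: (filter) -> detect -> response table."""
    use = ephys.bandpass_filter(rec) if noise_sd > 0 else rec
    spikes = ephys.detect_spikes(use, baseline_window=BASELINE_WINDOW)
    table = ephys.build_response_table(spikes, rec.stim_times,
                                       RESPONSE_WINDOW_MS, rec.stim_freqs)
    spont = ephys.spontaneous_spikes(spikes, rec.stim_times, RESPONSE_WINDOW_MS)
    return spikes, table, spont


def classify_unit(kind: str, seed: int, noise_sd: float = 0.0) -> str:
    """Simulate one unit archetype and classify it; returns the label."""
    params = _with_colliders(unit_params(kind, seed, noise_sd))
    rec, truth, _ = gen_recording(params)
    _, table, spont = analyze_recording(rec, noise_sd)
    flags = (
        ephys.check_constant_latency(table),
        ephys.check_frequency_following(table),
        ephys.collision_test(table, spont, params.unit_latency),
    )
    return ephys.classify_antidromic(*flags, responses=table).classification


def collision_outcome(blocking: bool, with_spont: bool, seed: int) -> bool | None:
    """Noise-free collision-test outcome for a blocked / non-blocked /
    silent unit (True / False / None expected respectively)."""
    params = SynthRecordingParams(seed=seed, stim_blocks=((5.0, 60),),
                                  noise_sd=0.0, latency_jitter_sd=0.0,
                                  response_prob=1.0,
                                  collision_blocking=blocking)
    if with_spont:
        params = _with_colliders(params, every=5)
    rec, _, _ = gen_recording(params)
    _, table, spont = analyze_recording(rec, 0.0)
    return ephys.collision_test(table, spont, params.unit_latency)


def recovery_run(seed: int, latency_ms: float, jitter_ms: float,
                 response_prob: float, n_stim: int = 100) -> dict:
    """Noise-free parameter-recovery run; returns truth and estimates."""
    params = SynthRecordingParams(seed=seed, stim_blocks=((5.0, n_stim),),
                                  noise_sd=0.0, unit_latency=latency_ms,
                                  latency_jitter_sd=jitter_ms,
                                  response_prob=response_prob)
    rec, truth, _ = gen_recording(params)
    _, table, _ = analyze_recording(rec, 0.0)
    responded = table["responded"]
    return {
        "n_stim": n_stim,
        "true_responded": int(truth["responded"].sum()),
        "detected_responded": int(responded.sum()),
        "efficiency_pct": ephys.efficiency(table),
        "true_latency_ms": latency_ms,
        "latency_mean_ms": float(table.loc[responded, "latency_ms"].mean())
        if responded.any() else float("nan"),
        "jitter_ms": jitter_ms,
        "rate": params.rate,
    }


def cohort_table(group_specs: dict[str, dict]) -> pd.DataFrame:
    """Per-animal cohort table from per-group totals.

    ``group_specs`` maps a group name to ``{"n_animals": int,
    "total_units": int, "n_respondent": int}``; units are apportioned as
    evenly as possible (the group mean is unaffected by apportionment).
    """
    rows = []
    for group, spec in group_specs.items():
        n, total = spec["n_animals"], spec["total_units"]
        base, extra = divmod(total, n)
        for i in range(n):
            rows.append({
                "animal": f"{group}-{i}",
                "group": group,
                "n_insertions": spec.get("n_insertions_per_animal", 4),
                "n_antidromic_units": base + (1 if i < extra else 0),
                "caudal_respondent": i < spec.get("n_respondent", 0),
            })
    return pd.DataFrame(rows)


def planted_efficiency_recording(n_stim: int, n_responses: int,
                                 latency_ms: float, seed: int,
                                 rate: float = 20000.0):
    """Recording where exactly ``n_responses`` of ``n_stim`` stimuli evoke
    a spike at ``latency_ms`` (which trials respond is randomised)."""
    from .simulate import spike_template

    rng = np.random.default_rng(seed)
    stim_times = 1.0 + np.arange(n_stim) * 1.0
    duration = stim_times[-1] + 0.5
    signal = np.zeros(int(duration * rate))
    template, peak = spike_template(rate, 100.0)
    chosen = rng.choice(n_stim, size=n_responses, replace=False)
    for i in chosen:
        t = stim_times[i] + latency_ms * 1e-3
        i0 = int(round(t * rate)) - peak
        signal[i0:i0 + template.size] += template
    return ephys.Recording(signal=signal, rate=rate, stim_times=stim_times)
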
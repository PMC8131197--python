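"""Calcium fluorescence traces generated from planted spiking activity.

A spike of unit magnitude adds an AR(1) calcium transient (instantaneous
rise, exponential decay) to the ROI trace.  The raw signal further carries a
constant offset, a slow sinusoidal drift, a shared neuropil contamination
component and white noise; the paired neuropil trace exposes the
contamination so the correction step can remove it.  No biophysical
indicator model beyond the AR(1) kernel is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import FluorescenceTrace

STIM_DURATION_S = 1.3
ITI_S = 3.0


def _ar1_convolve(spikes: np.ndarray, gamma: float) -> np.ndarray:
    """Causal AR(1) filter: c_t = gamma * c_{t-1} + s_t."""
    c = np.empty_like(spikes, dtype=float)
    acc = 0.0
    for t in range(len(spikes)):
        acc = gamma * acc + spikes[t]
        c[t] = acc
    return c


def simulate_fluorescence(
    spikes: np.ndarray,
    frame_rate: float = 10.0,
    decay_time_s: float = 0.7,
    amplitude: float = 1.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    neuropil_contamination: float = 0.7,
    drift_amplitude: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[FluorescenceTrace, np.ndarray]:
    """Fluorescence + neuropil trace pair from a spike train.

    ``spikes`` is the event magnitude per frame.  Returns the trace pair and
    the calcium transient (kernel-convolved spikes) as ground truth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spikes = np.asarray(spikes, dtype=float)
    if decay_time_s <= 0:
        raise ValueError("decay_time_s must be positive")
    n = len(spikes)
    gamma = float(np.exp(-1.0 / (decay_time_s * frame_rate)))
    calcium = amplitude * _ar1_convolve(spikes, gamma)
    t = np.arange(n) / frame_rate
    drift = drift_amplitude * np.sin(2 * np.pi * t / max(t[-1], 1.0)) if n > 1 else np.zeros(n)
    # slow neuropil signal shared between ROI and surround
    neuropil = 50.0 + 2.0 * np.sin(2 * np.pi * t / 37.0) + _ar1_convolve(
        rng.normal(scale=0.3, size=n), 0.95
    )
    F = (
        baseline
        + calcium
        + neuropil_contamination * neuropil
        + drift
        + (rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0)
    )
    Fneu = neuropil + (rng.normal(scale=0.1 * noise_sd, size=n) if noise_sd > 0 else 0.0)
    return FluorescenceTrace(F=F, Fneu=Fneu, frame_rate=frame_rate), calcium


@dataclass
class FluorescenceSim:
    """A simulated imaging session: traces, timeline and ground truth."""

    traces: list[FluorescenceTrace]
    windows: np.ndarray  # (n_trials, 2) stimulus on/off in s
    spikes: np.ndarray  # (n_neurons, n_frames) ground-truth event magnitudes
    frame_rate: float
    trials: pd.DataFrame


def simulate_session_fluorescence(
    trials: pd.DataFrame,
    rates: np.ndarray,
    frame_rate: float = 10.0,
    baseline_rate: float = 0.1,
    decay_time_s: float = 0.7,
    noise_sd: float = 0.5,
    neuropil_contamination: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> FluorescenceSim:
    """Expand trial-wise rates into a full-session recording.

    Spikes are Poisson per frame: rate = trial rate during the stimulus
    window, ``baseline_rate`` elsewhere.  Stimulus onsets follow a fixed
    trial grid (3 s inter-trial interval, 1.3 s stimulus).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    n_neurons, n_trials = rates.shape
    if n_trials != len(trials):
        raise ValueError("rates column count must equal trial count")
    trial_len = ITI_S + STIM_DURATION_S
    onsets = ITI_S + trial_len * np.arange(n_trials)
    windows = np.column_stack([onsets, onsets + STIM_DURATION_S])
    n_frames = int(np.ceil((onsets[-1] + STIM_DURATION_S + ITI_S) * frame_rate))
    t = np.arange(n_frames) / frame_rate

    frame_rate_drive = np.full((n_neurons, n_frames), baseline_rate)
    for i, (on, off) in enumerate(windows):
        sel = (t >= on) & (t < off)
        frame_rate_drive[:, sel] = rates[:, [i]]
    spikes = rng.poisson(np.clip(frame_rate_drive, 0, None) / frame_rate).astype(float)

    traces = []
    for i in range(n_neurons):
        tr, _ = simulate_fluorescence(
            spikes[i],
            frame_rate=frame_rate,
            decay_time_s=decay_time_s,
            noise_sd=noise_sd,
            neuropil_contamination=neuropil_contamination,
            seed=rng,
        )
        traces.append(tr)
    return FluorescenceSim(
        traces=traces, windows=windows, spikes=spikes, frame_rate=frame_rate, trials=trials
    )
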
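"""From raw ROI fluorescence to trial-wise inferred spike rates.

Stages mirror a standard two-photon pipeline: neuropil correction
(Fc = F - r * Fneu + r * median(Fneu), r = 0.7), dF/F against a running
25th-percentile baseline in a 60 s sliding window, non-negative deconvolution
under an AR(1) calcium kernel, and averaging of the inferred rate over the
stimulus presentation window of each trial.

The deconvolution solves

    min_s  1/2 || K s - y ||^2 + lam * sum(s)   s.t.  s >= 0

with K the causal AR(1) convolution matrix (kernel gamma^t), by an online
pool-adjacent-violators scheme (merging pools of frames that share one
calcium transient).  An optional event floor ``s_min`` greedily suppresses
events smaller than a noise-scaled threshold.  The decay gamma is estimated
from the trace autocovariance when not given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import welch


@dataclass
class FluorescenceTrace:
    """ROI fluorescence with its surrounding-neuropil signal."""

    F: np.ndarray
    Fneu: np.ndarray
    frame_rate: float
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.Fneu = np.asarray(self.Fneu, dtype=float)
        if self.F.shape != self.Fneu.shape:
            raise ValueError("F and Fneu must have the same length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.F)) / self.frame_rate


def neuropil_correct(trace: FluorescenceTrace, coefficient: float = 0.7) -> np.ndarray:
    """Fc = F - r * Fneu + r * median(Fneu); r defaults to 0.7.

    Re-adding the scaled median keeps the corrected trace on the original
    baseline level so the later dF/F baseline stays positive.
    """
    return trace.F - coefficient * trace.Fneu + coefficient * np.median(trace.Fneu)


def sliding_percentile(x: np.ndarray, window: int, percentile: float) -> np.ndarray:
    """Centered running percentile, window truncated at the edges."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window > n:
        raise ValueError("trace shorter than one window")
    half = window // 2
    out = np.empty(n)
    if n >= window:
        views = sliding_window_view(x, window)
        core = np.percentile(views, percentile, axis=1)
        starts = np.arange(n) - half
        interior = (starts >= 0) & (starts + window <= n)
        out[interior] = core[starts[interior]]
        for t in np.flatnonzero(~interior):
            lo, hi = max(0, t - half), min(n, t - half + window)
            out[t] = np.percentile(x[lo:hi], percentile)
    return out


def compute_dff(
    fc: np.ndarray, frame_rate: float, window_s: float = 60.0, percentile: float = 25.0
) -> np.ndarray:
    """dF/F = (Fc - F0) / F0 with F0 a running percentile baseline."""
    fc = np.asarray(fc, dtype=float)
    window = max(int(round(window_s * frame_rate)), 1)
    f0 = sliding_percentile(fc, window, percentile)
    if np.any(f0 <= 0):
        raise ValueError(
            "baseline F0 <= 0; add an offset to the fluorescence before dF/F"
        )
    return (fc - f0) / f0


# ---------------------------------------------------------------------------
# non-negative AR(1) deconvolution

def estimate_noise_sd(y: np.ndarray, frame_rate: float) -> float:
    """Noise sd from the high-frequency half of the power spectrum."""
    y = np.asarray(y, dtype=float)
    nperseg = min(256, len(y))
    freqs, psd = welch(y, fs=frame_rate, nperseg=nperseg)
    band = freqs >= frame_rate / 4
    if not band.any():
        return float(np.std(np.diff(y)) / np.sqrt(2)) if len(y) > 1 else 0.0
    return float(np.sqrt(psd[band].mean() * frame_rate / 2))


def estimate_decay(y: np.ndarray, lo: float = 0.5, hi: float = 0.98) -> float:
    """AR(1) decay from the lag-2 / lag-1 autocovariance ratio, clamped."""
    y = np.asarray(y, dtype=float) - np.mean(y)
    if len(y) < 3:
        return (lo + hi) / 2
    c1 = float(np.dot(y[:-1], y[1:]))
    c2 = float(np.dot(y[:-2], y[2:]))
    if c1 <= 0:
        return lo
    return float(np.clip(c2 / c1, lo, hi))


def _oasis(y: np.ndarray, gamma: float, lam: float, s_min: float) -> np.ndarray:
    """Pool-adjacent-violators solver for the penalized AR(1) problem."""
    n = len(y)
    # L1 penalty folds into a shift of the observations
    ytilde = y - lam * (1 - gamma)
    if n:
        ytilde = ytilde.copy()
        ytilde[-1] = y[-1] - lam
    # each pool: [num, den, start, length]; value v = num / den
    pools: list[list[float]] = []
    for t in range(n):
        pools.append([ytilde[t], 1.0, t, 1])
        while len(pools) > 1:
            vb = pools[-1][0] / pools[-1][1]
            va = pools[-2][0] / pools[-2][1]
            la = pools[-2][3]
            floor = gamma**la * va + s_min if va > 0 else 0.0
            if vb >= floor:
                break
            num_b, den_b, _, lb = pools.pop()
            pools[-1][0] += gamma**la * num_b
            pools[-1][1] += gamma ** (2 * la) * den_b
            pools[-1][3] = la + lb
    c = np.zeros(n)
    for num, den, start, length in pools:
        v = max(num / den, 0.0)
        c[start : start + length] = v * gamma ** np.arange(length)
    s = np.empty(n)
    if n:
        s[0] = c[0]
        s[1:] = c[1:] - gamma * c[:-1]
    return np.clip(s, 0.0, None)


def infer_spikes(
    dff: np.ndarray,
    frame_rate: float,
    gamma: float | None = None,
    lam: float = 0.0,
    s_min: float | None = None,
) -> np.ndarray:
    """Non-negative deconvolution of a dF/F trace into event magnitudes.

    Parameters
    ----------
    gamma : float, optional
        AR(1) decay per frame; estimated from the autocovariance (clamped to
        [0.5, 0.98]) when omitted.
    lam : float, default 0
        L1 sparsity penalty on event magnitudes.
    s_min : float, optional
        Event floor; events smaller than this are greedily merged away.
        Defaults to 3x the estimated noise sd (0 disables).

    Returns the inferred event magnitude per frame (a.u.); an all-zero trace
    yields an all-zero output.
    """
    y = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    if len(y) == 0 or not np.any(y):
        return np.zeros_like(y)
    if gamma is None:
        gamma = estimate_decay(y)
    if s_min is None:
        s_min = 3.0 * estimate_noise_sd(y, frame_rate)
    return _oasis(y, gamma, lam, s_min)


def infer_rate(dff: np.ndarray, frame_rate: float, **kwargs) -> np.ndarray:
    """Inferred spike rate per frame (event magnitude times frame rate)."""
    return infer_spikes(dff, frame_rate, **kwargs) * frame_rate


# ---------------------------------------------------------------------------
# trial windows and licks

def extract_trial_responses(
    rate: np.ndarray,
    timestamps: np.ndarray,
    windows: np.ndarray,
) -> np.ndarray:
    """Mean rate per trial over frames with timestamp in [on, off).

    ``rate`` is (n_frames,) or (n_neurons, n_frames); ``windows`` is
    (n_trials, 2) of [stimulus on, stimulus off) times in seconds.
    """
    rate = np.atleast_2d(np.asarray(rate, dtype=float))
    timestamps = np.asarray(timestamps, dtype=float)
    windows = np.asarray(windows, dtype=float)
    out = np.empty((rate.shape[0], len(windows)))
    for i, (on, off) in enumerate(windows):
        sel = (timestamps >= on) & (timestamps < off)
        if not sel.any():
            raise ValueError(f"trial {i}: no frames in window [{on}, {off})")
        out[:, i] = rate[:, sel].mean(axis=1)
    return out if out.shape[0] > 1 else out[0]


def detect_lick_bouts(lick_times: np.ndarray, max_gap: float = 0.5) -> np.ndarray:
    """Onsets of lick-bouts: runs of licks with inter-lick gaps <= max_gap.

    A lick belongs to the running bout when it occurs within 500 ms of the
    previous lick (inclusive); the bout onset is its first lick.
    """
    t = np.asarray(lick_times, dtype=float)
    if len(t) == 0:
        return np.empty(0)
    if np.any(np.diff(t) < 0):
        raise ValueError("lick timestamps must be sorted")
    new_bout = np.concatenate([[True], np.diff(t) > max_gap])
    return t[new_bout]


def lick_triggered_average(
    rate: np.ndarray,
    timestamps: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float] = (-1.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate segment centered on lick-bout onsets.

    Segments that would extend past either end of the recording are dropped;
    raises if no onset leaves a usable segment.  Returns (lags_s, average).
    """
    rate = np.asarray(rate, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("need at least one lick-bout onset")
    dt = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    segments = []
    for on in onsets:
        center = int(round((on - timestamps[0]) / dt))
        if center - pre < 0 or center + post >= len(rate):
            continue
        segments.append(rate[center - pre : center + post + 1])
    if not segments:
        raise ValueError("no onset leaves a complete segment within the recording")
    lags = (np.arange(-pre, post + 1)) * dt
    return lags, np.mean(segments, axis=0)


def preprocess_session(
    traces: list[FluorescenceTrace],
    windows: np.ndarray,
    neuropil_coefficient: float = 0.7,
    dff_window_s: float = 60.0,
    dff_percentile: float = 25.0,
    **deconv_kwargs,
) -> np.ndarray:
    """Full pipeline for one session: (n_neurons, n_trials) inferred rates."""
    rows = []
    for tr in traces:
        fc = neuropil_correct(tr, neuropil_coefficient)
        dff = compute_dff(fc, tr.frame_rate, dff_window_s, dff_percentile)
        rate = infer_rate(dff, tr.frame_rate, **deconv_kwargs)
        rows.append(extract_trial_responses(rate, tr.timestamps, windows))
    return np.vstack(rows)
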
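"""Generate rule-governed Go/NoGo behavior with a calibrated sensitivity.

The mouse's choice is modelled as a logistic function of the signed rank
distance of the presented stimulus to the category boundary along the
rule-relevant feature.  The logistic slope is solved numerically so that the
session's expected d' matches a requested target; the bias is zero, which on
the symmetric grids makes hit and correct-rejection rates mirror images.

Stimuli are presented in pseudorandom order with never more than three
stimuli of the same category in a row, enforced by constrained sequential
sampling with a mild self-balancing term that keeps category frequencies
near one half in any window of a few hundred trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from ..stimuli import BOUNDARY, GO, NOGO, CategoryRule

MAX_RUN = 3  # no more than three same-category stimuli in a row
_BALANCE_GAIN = 0.02


def _calibrate_slope(dist: np.ndarray, labels: np.ndarray, target_dprime: float) -> float:
    """Solve the logistic slope so the expected session d' hits the target.

    Expected hit rate is the mean Go probability over Go-category stimuli
    (uniform presentation), expected false-alarm rate the mean over NoGo
    stimuli; d' = z(H) - z(F) is monotone in the slope.
    """
    if target_dprime < 0:
        raise ValueError("target_dprime must be >= 0")
    if target_dprime == 0:
        return 0.0
    d_go = dist[labels == GO]
    d_nogo = dist[labels == NOGO]

    def expected_dprime(k: float) -> float:
        h = float(np.clip(expit(k * d_go).mean(), 1e-9, 1 - 1e-9))
        f = float(np.clip(expit(k * d_nogo).mean(), 1e-9, 1 - 1e-9))
        return norm.ppf(h) - norm.ppf(f)

    lo, hi = 0.0, 1.0
    while expected_dprime(hi) < target_dprime:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"target_dprime {target_dprime} is not attainable")
    return brentq(lambda k: expected_dprime(k) - target_dprime, lo, hi, xtol=1e-10)


def _category_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 category sequence, max run length 3, self-balancing."""
    seq = np.empty(n_trials, dtype=int)
    run = 0
    last = -1
    n_go = 0
    for t in range(n_trials):
        p_go = 0.5 + _BALANCE_GAIN * ((t - n_go) - n_go)
        p_go = float(np.clip(p_go, 0.05, 0.95))
        if run >= MAX_RUN:
            c = 1 - last
        else:
            c = int(rng.random() < p_go)
        run = run + 1 if c == last else 1
        last = c
        n_go += c
        seq[t] = c
    return seq


def _lick_times(rng: np.random.Generator, lick_rate: float, bout_duration: float) -> list[float]:
    """Poisson lick burst after stimulus onset on Go-choice trials (s)."""
    reaction = 0.2 + rng.lognormal(mean=np.log(0.25), sigma=0.3)
    n_licks = 1 + rng.poisson(lick_rate * bout_duration)
    gaps = rng.exponential(1.0 / lick_rate, size=n_licks - 1)
    return np.concatenate([[reaction], reaction + np.cumsum(gaps)]).round(4).tolist()


def simulate_behavior(
    rule: CategoryRule,
    target_dprime: float,
    n_trials: int,
    seed: int | np.random.Generator,
    stimulus_ids: np.ndarray | None = None,
    lick_rate: float = 8.0,
    speed_mean: float = 6.0,
    speed_sd: float = 2.0,
    session: str = "S1",
    timepoint: str = "T5",
) -> pd.DataFrame:
    """Simulate one behavioral session as a trial table.

    Parameters
    ----------
    rule : CategoryRule
        Active category rule (defines the presented stimulus space, the
        relevant feature and the boundary).
    target_dprime : float
        Desired session sensitivity; the logistic choice model is calibrated
        so the expected d' equals this value.
    n_trials : int
        Number of trials.
    seed : int or Generator
        Randomness source.
    stimulus_ids : array-like, optional
        Restrict presentation to a subset of stimuli (training stages use
        growing subsets); default presents the full space.

    Returns
    -------
    DataFrame with one row per trial: stimulus identity and features,
    category under the rule, resolved category (boundary stimuli are assigned
    to a random category each presentation), choice, outcome, reward, lick
    times, running speed and session metadata.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = rule.labels()
    dist = rule.signed_distance()
    stim_table = rule.space.table()

    if stimulus_ids is None:
        stimulus_ids = np.arange(rule.space.n_stimuli)
    stimulus_ids = np.asarray(stimulus_ids, dtype=int)
    sub_labels = labels[stimulus_ids]
    # boundary stimuli belong to both categories
    go_pool = stimulus_ids[np.isin(sub_labels, [GO, BOUNDARY])]
    nogo_pool = stimulus_ids[np.isin(sub_labels, [NOGO, BOUNDARY])]
    if len(go_pool) == 0 or len(nogo_pool) == 0:
        raise ValueError("each category needs at least one presentable stimulus")

    # calibrate on the presented non-boundary stimuli (uniform within
    # category); session d' is computed on Go/NoGo-category trials only
    true_go = stimulus_ids[sub_labels == GO]
    true_nogo = stimulus_ids[sub_labels == NOGO]
    pres_labels = np.concatenate([np.full(len(true_go), GO), np.full(len(true_nogo), NOGO)])
    pres_dist = np.concatenate([dist[true_go], dist[true_nogo]])
    slope = _calibrate_slope(pres_dist, pres_labels, target_dprime)

    cats = _category_sequence(n_trials, rng)
    stim = np.where(
        cats == 1,
        go_pool[rng.integers(len(go_pool), size=n_trials)],
        nogo_pool[rng.integers(len(nogo_pool), size=n_trials)],
    )
    assigned = np.where(cats == 1, GO, NOGO)
    p_go = expit(slope * dist[stim])
    choice_go = rng.random(n_trials) < p_go

    hit = (assigned == GO) & choice_go
    miss = (assigned == GO) & ~choice_go
    fa = (assigned == NOGO) & choice_go
    outcome = np.where(hit, "hit", np.where(miss, "miss", np.where(fa, "false_alarm", "correct_rejection")))

    speed = np.clip(rng.normal(speed_mean, speed_sd, size=n_trials), 0.0, None)
    licks = [
        _lick_times(rng, lick_rate, bout_duration=0.8) if c else []
        for c in choice_go
    ]

    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "stimulus_id": stim,
            "orientation": stim_table["orientation"].to_numpy()[stim],
            "spatial_frequency": stim_table["spatial_frequency"].to_numpy()[stim],
            "category": labels[stim],
            "assigned_category": assigned,
            "choice": np.where(choice_go, GO, NOGO),
            "outcome": outcome,
            "rewarded": hit,
            "lick_times": licks,
            "running_speed": speed,
            "session": session,
            "timepoint": timepoint,
        }
    )
    return table


def generate_uninstructed_behaviors(
    trials: pd.DataFrame,
    rng: int | np.random.Generator,
    names: tuple[str, ...] = ("pupil_diameter", "eye_position", "eyelid_opening", "paw_angle", "body_elongation"),
    ar_coef: float = 0.9,
    choice_coupling: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Smooth autoregressive trial-wise predictors emulating pose-tracking output.

    Each predictor is a standardized AR(1) process over trials; entries of
    ``choice_coupling`` add a choice-locked component (e.g. pupil dilation on
    Go trials) so variance-partitioning analyses have known structure.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(trials)
    choice = (trials["choice"] == GO).to_numpy().astype(float)
    out = {}
    for name in names:
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(scale=np.sqrt(1 - ar_coef**2), size=n)
        for t in range(1, n):
            x[t] = ar_coef * x[t - 1] + innov[t]
        if choice_coupling and name in choice_coupling:
            x = x + choice_coupling[name] * (choice - choice.mean())
        out[name] = (x - x.mean()) / x.std()
    return pd.DataFrame(out, index=trials.index)
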
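"""Behavioral quantification of Go/NoGo categorization.

Sensitivity is the signal-detection index d' = z(hit rate) - z(false-alarm
rate); hit rate is the fraction of Go-category trials with a Go lick,
false-alarm rate the fraction of NoGo-category trials with a Go lick.  Rates
of exactly 0 or 1 are clipped to 1/(2N) and 1 - 1/(2N) before the inverse
normal transform (N = trials of that category), standard psychophysics
practice for perfect sessions.

Learning curves (d' per session) are fitted with the sigmoid
``y(x) = p1 + p2 / (1 + exp(p3 (x - p4)))`` with the minimum p1 fixed at 0;
p2 is the asymptote, p3 the slope and p4 the inflection session.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .stimuli import BOUNDARY, GO, NOGO, CategoryRule

NOT_REACHED = None


def _clip_rate(k: int, n: int) -> float:
    """Proportion k/n with 0 and 1 clipped to 1/(2n) and 1 - 1/(2n)."""
    if n == 0:
        raise ValueError("no trials for rate")
    return float(np.clip(k / n, 1 / (2 * n), 1 - 1 / (2 * n)))


def hit_and_fa_rates(trials: pd.DataFrame) -> tuple[float, float]:
    """Clipped hit and false-alarm rates (boundary-category trials excluded)."""
    cat = trials["category"]
    go_trials = trials[cat == GO]
    nogo_trials = trials[cat == NOGO]
    for name, sub in (("Go", go_trials), ("NoGo", nogo_trials)):
        if len(sub) == 0:
            raise ValueError(f"no trials of the {name} category")
    hits = int((go_trials["choice"] == GO).sum())
    fas = int((nogo_trials["choice"] == GO).sum())
    return _clip_rate(hits, len(go_trials)), _clip_rate(fas, len(nogo_trials))


def compute_dprime(trials: pd.DataFrame) -> float:
    """Session d' = z(hit rate) - z(false-alarm rate)."""
    h, f = hit_and_fa_rates(trials)
    return float(norm.ppf(h) - norm.ppf(f))


def dprime_from_counts(hits: int, n_go: int, fas: int, n_nogo: int) -> float:
    """d' from raw counts, with the same extreme-rate clipping."""
    return float(norm.ppf(_clip_rate(hits, n_go)) - norm.ppf(_clip_rate(fas, n_nogo)))


def fraction_correct_go(trials: pd.DataFrame) -> float:
    """Hits / (hits + false alarms): accuracy among Go choices."""
    outcome = trials["outcome"]
    hits = int((outcome == "hit").sum())
    fas = int((outcome == "false_alarm").sum())
    if hits + fas == 0:
        raise ValueError("no Go-choice trials; fraction correct Go is undefined")
    return hits / (hits + fas)


def fraction_chosen_map(trials: pd.DataFrame, space) -> pd.Series:
    """Per-stimulus fraction of presentations answered with a Go choice.

    Indexed by stimulus id over the full space; stimuli never presented are
    NaN (absent), not 0.
    """
    go = (trials["choice"] == GO).groupby(trials["stimulus_id"]).mean()
    return go.reindex(np.arange(space.n_stimuli))


def psychometric_curves(
    chosen_map: pd.Series, rule: CategoryRule
) -> tuple[pd.Series, pd.Series]:
    """Fraction chosen along the relevant and the irrelevant feature.

    Each curve averages the per-stimulus fraction-chosen values across the
    other feature's levels; curves are indexed by feature value ordered by
    signed distance to the boundary (relevant) or feature order (irrelevant).
    Levels with no presented stimulus are absent from the curve.
    """
    table = rule.space.table()
    df = pd.DataFrame(
        {
            "chosen": chosen_map.to_numpy(),
            "relevant": table[rule.relevant_feature].to_numpy(),
            "irrelevant": table[rule.irrelevant_feature].to_numpy(),
        }
    )
    rel = df.groupby("relevant")["chosen"].mean().dropna()
    irr = df.groupby("irrelevant")["chosen"].mean().dropna()
    if rule.go_side == "below":
        rel = rel.iloc[::-1]
    return rel, irr


# ---------------------------------------------------------------------------
# learning curves

def _sigmoid(x, p1, p2, p3, p4):
    return p1 + p2 / (1.0 + np.exp(p3 * (x - p4)))


class SigmoidLearningCurve(RegressorMixin, BaseEstimator):
    """Sigmoid fit of a learning curve, y(x) = p1 + p2/(1 + e^{p3 (x - p4)}).

    Parameters
    ----------
    fix_minimum : bool, default True
        Freeze the minimum p1 at a d' of 0 (naive performance is chance).
    n_starts : int, default 5
        Multi-start nonlinear least squares over plausible slope/inflection
        ranges, to avoid local minima.

    Attributes
    ----------
    p1_, p2_, p3_, p4_ : float
        Fitted minimum, maximum, slope and inflection point.
    rmse_ : float
        Root-mean-square error between data and fit (``inf`` when no start
        converged).
    converged_ : bool
    """

    def __init__(self, fix_minimum: bool = True, n_starts: int = 5, tol: float = 1e-8):
        self.fix_minimum = fix_minimum
        self.n_starts = n_starts
        self.tol = tol

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValueError("x and y must have the same length")
        if len(x) < 4:
            raise ValueError("need at least 4 sessions to fit a learning curve")
        amp = y.max() if y.max() > 0 else 1.0
        slopes = np.linspace(-2.0, -0.1, self.n_starts)
        inflections = np.quantile(x, np.linspace(0.15, 0.85, self.n_starts))
        best = None
        for p3_0, p4_0 in zip(slopes, inflections):
            if self.fix_minimum:
                f = lambda x_, p2, p3, p4: _sigmoid(x_, 0.0, p2, p3, p4)
                p0 = [amp, p3_0, p4_0]
            else:
                f = _sigmoid
                p0 = [0.0, amp, p3_0, p4_0]
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    popt, _ = curve_fit(
                        f, x, y, p0=p0, maxfev=20000, ftol=self.tol, xtol=self.tol
                    )
            except (RuntimeError, ValueError):
                continue
            resid = y - f(x, *popt)
            rmse = float(np.sqrt(np.mean(resid**2)))
            if best is None or rmse < best[0]:
                best = (rmse, popt)
        if best is None:
            self.p1_, self.p2_, self.p3_, self.p4_ = 0.0, np.nan, np.nan, np.nan
            self.rmse_ = np.inf
            self.converged_ = False
            return self
        rmse, popt = best
        if self.fix_minimum:
            self.p1_ = 0.0
            self.p2_, self.p3_, self.p4_ = map(float, popt)
        else:
            self.p1_, self.p2_, self.p3_, self.p4_ = map(float, popt)
        self.rmse_ = rmse
        self.converged_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "rmse_")
        x = np.asarray(X, dtype=float).ravel()
        return _sigmoid(x, self.p1_, self.p2_, self.p3_, self.p4_)


def fit_learning_curve(dprime_by_session: Sequence[float], fix_minimum: bool = True) -> SigmoidLearningCurve:
    """Fit the sigmoid learning curve to a d' series (session index 1..n)."""
    y = np.asarray(dprime_by_session, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    return SigmoidLearningCurve(fix_minimum=fix_minimum).fit(x, y)


def sessions_to_criterion(
    fractions_correct_go: Sequence[float], criterion: float = 0.66
) -> int | None:
    """1-based index of the first session *strictly* exceeding the criterion.

    Returns None when the criterion is never reached.  Pre-training sessions
    (no visual stimulation) must be excluded by the caller.
    """
    for i, frac in enumerate(fractions_correct_go, start=1):
        if frac > criterion:
            return i
    return NOT_REACHED


def dprime_learning_curve(session_tables: Sequence[pd.DataFrame]) -> pd.Series:
    """d' per time point; two sessions at one time point are averaged.

    When two imaging regions were recorded at a time point the displayed
    value is the mean of the two sessions' d'.
    """
    rows = [
        {"timepoint": t["timepoint"].iloc[0], "dprime": compute_dprime(t)}
        for t in session_tables
    ]
    df = pd.DataFrame(rows)
    order = df["timepoint"].drop_duplicates().tolist()
    return df.groupby("timepoint")["dprime"].mean().reindex(order)
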
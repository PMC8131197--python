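"""Category selectivity of single neurons.

The category-tuning index (CTI) contrasts a neuron's response differences
*across* the category boundary with those *within* each category.  With
``r_i`` the mean inferred spike rate for stimulus ``i``,

    within  = mean over same-category stimulus pairs of |r_i - r_j|
    across  = mean over cross-category pairs of |r_i - r_j|
    CTI     = (across - within) / (across + within)

ranging from -1 to 1: an ideal category cell (identical response to every
stimulus of one category, a different identical response to the other) has
CTI 1; a cell with no category structure sits near or below 0.  Within-pairs
are pooled over both categories.  A silent or perfectly uniform cell (0/0)
is assigned CTI 0.

Neurons with CTI > 0.1 count as category-selective; the preferred category
is the one with the higher mean rate over trials.  At time points where only
part of the grid is shown the CTI is undefined and selectivity is
approximated by a contrast index of the Go/NoGo trial means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import GO, NOGO, CategoryRule

logger = logging.getLogger(__name__)

CTI_THRESHOLD = 0.1


# ---------------------------------------------------------------------------
# category-tuning index

def _mean_abs_pairwise(values: np.ndarray) -> tuple[float, int]:
    """Sum and count of |v_i - v_j| over unordered pairs."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        return 0.0, 0
    # sum over pairs of |v_i - v_j| = sum_k (2k - n + 1) v_(k) for sorted v
    coeff = 2 * np.arange(n) - n + 1
    return float(np.dot(coeff, v)), n * (n - 1) // 2


def compute_cti(stimulus_rates: np.ndarray, rule: CategoryRule) -> float:
    """CTI from per-stimulus mean rates on the full grid.

    ``stimulus_rates`` is indexed by stimulus id.  Requires at least two
    stimuli with a rate in each category; boundary-labelled stimuli (dense
    grid) are excluded.  Missing stimuli may be encoded as NaN.
    """
    rates = np.asarray(stimulus_rates, dtype=float)
    labels = rule.labels()
    if len(rates) != len(labels):
        raise ValueError("stimulus_rates must have one entry per stimulus id")
    go = rates[(labels == GO) & ~np.isnan(rates)]
    nogo = rates[(labels == NOGO) & ~np.isnan(rates)]
    if len(go) < 2 or len(nogo) < 2:
        raise ValueError(
            f"CTI needs >=2 stimuli per category with responses "
            f"(got {len(go)} Go, {len(nogo)} NoGo)"
        )
    s_go, n_go = _mean_abs_pairwise(go)
    s_nogo, n_nogo = _mean_abs_pairwise(nogo)
    within = max((s_go + s_nogo) / (n_go + n_nogo), 0.0)
    across = float(np.abs(go[:, None] - nogo[None, :]).mean())
    denom = across + within
    # a silent or perfectly uniform cell has no pairwise structure at all
    if denom <= 1e-12 * max(1.0, float(np.abs(np.concatenate([go, nogo])).max())):
        return 0.0
    return (across - within) / denom


def approximate_category_selectivity(trial_rates: np.ndarray, is_go: np.ndarray) -> float:
    """Contrast index of category trial means, for partial-grid time points.

    (mean Go - mean NoGo) / (mean Go + mean NoGo); 0/0 -> 0.  Only an
    approximation of category tuning — never mixed with full-grid CTIs in
    one comparison.
    """
    trial_rates = np.asarray(trial_rates, dtype=float)
    is_go = np.asarray(is_go, dtype=bool)
    if not is_go.any() or is_go.all():
        raise ValueError("need at least one trial of each category")
    m_go = trial_rates[is_go].mean()
    m_nogo = trial_rates[~is_go].mean()
    denom = m_go + m_nogo
    if denom == 0:
        return 0.0
    return float((m_go - m_nogo) / denom)


def classify_selective(
    cti: np.ndarray,
    mean_rate_go: np.ndarray,
    mean_rate_nogo: np.ndarray,
    threshold: float = CTI_THRESHOLD,
) -> pd.DataFrame:
    """Selective flag (CTI strictly above threshold) and preferred category.

    Exact Go/NoGo rate ties leave the preference undefined (NaN); their count
    is logged so population splits remain accountable.
    """
    cti = np.asarray(cti, dtype=float)
    diff = np.asarray(mean_rate_go, dtype=float) - np.asarray(mean_rate_nogo, dtype=float)
    pref = np.where(diff > 0, GO, np.where(diff < 0, NOGO, None))
    n_ties = int((diff == 0).sum())
    if n_ties:
        logger.warning("%d neurons with exact Go/NoGo rate ties; preference undefined", n_ties)
    return pd.DataFrame(
        {"cti": cti, "selective": cti > threshold, "preferred_category": pref}
    )


def fraction_selective(selective: np.ndarray, regions: np.ndarray) -> pd.Series:
    """Per-region fraction of selective neurons among all tracked neurons."""
    df = pd.DataFrame({"selective": np.asarray(selective, dtype=bool), "region": regions})
    counts = df.groupby("region")["selective"].agg(["mean", "size"])
    empty = counts["size"] == 0
    if empty.any():
        logger.warning("empty regions excluded: %s", list(counts.index[empty]))
    return counts.loc[~empty, "mean"]


def population_overlap(
    set_a: np.ndarray,
    set_b: np.ndarray,
    n_total: int,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[int, float]:
    """Observed overlap of two selective populations vs an identity-shuffle null.

    The null preserves |A| and |B| but shuffles neuron identities; returns
    (|A ∩ B|, 95th percentile of the shuffled overlap distribution).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.unique(np.asarray(set_a, dtype=int))
    b = np.unique(np.asarray(set_b, dtype=int))
    if len(a) == 0 or len(b) == 0:
        logger.warning("empty selective set: overlap 0, degenerate null")
        return 0, 0.0
    observed = len(np.intersect1d(a, b, assume_unique=True))
    null = np.empty(n_shuffles)
    ids = np.arange(n_total)
    for s in range(n_shuffles):
        pa = rng.choice(ids, size=len(a), replace=False)
        pb = rng.choice(ids, size=len(b), replace=False)
        null[s] = len(np.intersect1d(pa, pb, assume_unique=True))
    return observed, float(np.percentile(null, 95))


# ---------------------------------------------------------------------------
# selectivity time course

@dataclass(frozen=True)
class TimeCourseTemplates:
    """Characteristic selectivity time courses over the imaging time points.

    Values are normalized to [0, 1] with no selectivity = 0 (all templates
    are 0 at the naive time point) and maximum selectivity = 1.

    adhoc : acquired with the first rewarded training and stable throughout
            (choice / reward associations survive the rule switch).
    rule1 : grows with the categorization demand of rule 1, peaks at the
            rule-1 generalization test, decays after the rule switch.
    rule2 : flat through rule-1 training, grows during rule-2 training.
    """

    adhoc: np.ndarray
    rule1: np.ndarray
    rule2: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.adhoc, self.rule1, self.rule2])


def default_templates(n_timepoints: int = 8) -> TimeCourseTemplates:
    if n_timepoints != 8:
        raise ValueError("default templates are defined for the 8-point series")
    return TimeCourseTemplates(
        adhoc=np.array([0, 1, 1, 1, 1, 1, 1, 1], dtype=float),
        rule1=np.array([0, 0.25, 0.5, 0.75, 1.0, 0.5, 0.25, 0.0]),
        rule2=np.array([0, 0, 0, 0, 0, 1 / 3, 2 / 3, 1.0]),
    )


def selectivity_timecourse(sessions) -> np.ndarray:
    """Per-neuron signed selectivity (mean Go - mean NoGo rate) per time point.

    ``sessions`` is the learning series (objects with ``trials``, ``rates``
    and the rule active at that time point); category labels follow the
    active rule.  Only neurons tracked in every session enter (the rate
    matrices share neuron identity by construction).
    """
    values = []
    for s in sessions:
        labels = s.rule.labels()
        stim_cat = labels[s.trials["stimulus_id"].to_numpy()]
        is_go = np.where(
            stim_cat == "boundary",
            (s.trials["assigned_category"] == GO).to_numpy(),
            stim_cat == GO,
        )
        values.append(s.rates[:, is_go].mean(axis=1) - s.rates[:, ~is_go].mean(axis=1))
    return np.column_stack(values)


def fit_timecourse_templates(
    timecourses: np.ndarray,
    templates: TimeCourseTemplates | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress each neuron's selectivity time course on the three templates.

    Ordinary least squares with intercept.  A neuron is assigned to the
    template with the largest positive weight when that weight is
    significant (two-sided t-test at ``alpha``); otherwise 'none'.
    """
    timecourses = np.atleast_2d(np.asarray(timecourses, dtype=float))
    templates = templates if templates is not None else default_templates(timecourses.shape[1])
    X = np.column_stack([np.ones(timecourses.shape[1]), templates.matrix()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("templates are collinear; fit is not identifiable")
    from scipy import stats

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = timecourses @ X @ xtx_inv.T  # (n_neurons, 4)
    resid = timecourses - beta @ X.T
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / max(dof, 1)
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df=max(dof, 1))
    names = np.array(["adhoc", "rule1", "rule2"])
    w = beta[:, 1:]
    p = pvals[:, 1:]
    best = np.argmax(w, axis=1)
    rows = np.arange(len(w))
    assigned = np.where(
        (w[rows, best] > 0) & (p[rows, best] < alpha), names[best], "none"
    )
    out = pd.DataFrame(w, columns=[f"w_{n}" for n in names])
    out["intercept"] = beta[:, 0]
    out["assigned_template"] = assigned
    return out
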
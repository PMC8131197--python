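"""Trial-wise encoding models of single-neuron activity.

A multilinear regression predicts each neuron's trial-wise mean inferred
spike rate from task variables (stimulus category, choice, reward as 0/1
predictors; running speed continuous).  A positive weight means higher
activity in trials where the predictor is higher.  Weights are normalized
for overall response-amplitude differences either by the sum of absolute
weights including the intercept (rule-switch analysis) or by the maximum
weight (task-change analysis).

Functional cell types are found by agglomerative clustering of the
normalized weight vectors (neurons with R^2 > 0.05), with the number of
clusters chosen by the gap statistic: the smallest k with
Gap(k) >= Gapmax - s.e.(Gapmax), referenced against uniform draws over the
observed feature bounding box.

The task-change analysis (Go/NoGo -> left/right) uses forward-backward
stepwise selection with partial F-tests over {category, Go, reward,
GoRight, GoLeft}; the influence of instructed vs uninstructed behaviors is
quantified by cross-validated variance partitioning (cvR^2: everything else
shuffled; delta R^2: full R^2 minus the R^2 with the predictor of interest
shuffled).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .stimuli import GO


# ---------------------------------------------------------------------------
# ordinary least squares with partial F-tests

class TrialGLM(RegressorMixin, BaseEstimator):
    """OLS encoding model with per-predictor partial F-tests.

    Attributes
    ----------
    coef_ : ndarray (n_predictors,)
    intercept_ : float
    r2_ : float
    f_pvalues_ : ndarray (n_predictors,)
        Partial F-test p-value for dropping each predictor from the full
        model.
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    """

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 10:
            raise ValueError("need at least 10 trials")
        if n != len(y):
            raise ValueError("X and y length mismatch")
        const = X.std(axis=0) == 0
        if const.any():
            bad = [names[i] if names else i for i in np.flatnonzero(const)]
            raise ValueError(f"constant predictors: {bad}")
        design = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            bad = _collinear_columns(design, names)
            raise ValueError(f"rank-deficient design; collinear predictors: {bad}")
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.r2_ = 1 - rss / tss if tss > 0 else 0.0
        dof = n - design.shape[1]
        pvals = np.empty(p)
        for j in range(p):
            reduced = np.delete(design, j + 1, axis=1)
            b_r, _, _, _ = np.linalg.lstsq(reduced, y, rcond=None)
            rss_r = float(np.sum((y - reduced @ b_r) ** 2))
            if rss <= 0:
                pvals[j] = 0.0 if rss_r > rss else 1.0
                continue
            f = (rss_r - rss) / (rss / dof)
            pvals[j] = stats.f.sf(f, 1, dof)
        self.f_pvalues_ = pvals
        if names is not None:
            self.feature_names_in_ = np.array(names)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


def _collinear_columns(design: np.ndarray, names) -> list:
    bad = []
    base_rank = np.linalg.matrix_rank(design)
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == base_rank:
            bad.append(names[j - 1] if names else j - 1)
    return bad


def fit_trial_glm(
    rates: np.ndarray, predictors: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Fit the encoding model to every neuron.

    ``rates`` is (n_neurons, n_trials); returns one row per neuron with raw
    weights ``w_<name>``, intercept, R^2, per-predictor significance flags
    and sum-normalized weights ``nw_<name>`` (plus ``nw_intercept``).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    rows = []
    for y in rates:
        m = TrialGLM().fit(predictors, y)
        weights = dict(zip(predictors.columns, m.coef_))
        norm = normalize_weights(
            {"intercept": m.intercept_, **weights}, mode="sum"
        )
        rows.append(
            {
                **{f"w_{k}": v for k, v in weights.items()},
                "intercept": m.intercept_,
                "r2": m.r2_,
                **{f"p_{k}": p for k, p in zip(predictors.columns, m.f_pvalues_)},
                **{f"sig_{k}": p < alpha for k, p in zip(predictors.columns, m.f_pvalues_)},
                **{f"nw_{k}": v for k, v in norm.items()},
            }
        )
    return pd.DataFrame(rows)


def normalize_weights(weights: dict[str, float], mode: str) -> dict[str, float]:
    """Normalize predictor weights for response-amplitude differences.

    mode "sum": divide by the sum of absolute weights including the
    intercept (then absolute normalized weights sum to 1).  mode "max":
    divide by the maximum weight (largest normalized weight becomes 1).
    """
    values = np.array(list(weights.values()), dtype=float)
    if mode == "sum":
        denom = np.abs(values).sum()
    elif mode == "max":
        denom = values.max()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise ValueError("all-zero weights cannot be normalized")
    return {k: float(v / denom) for k, v in zip(weights, values)}


# ---------------------------------------------------------------------------
# gap-statistic hierarchical clustering

def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


class GapStatisticClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering with gap-statistic model selection.

    The dendrogram is cut at every k up to ``k_max``; for each k the log
    within-cluster dispersion is compared with its expectation over
    ``b_reference`` uniform reference datasets drawn over the observed
    bounding box.  The chosen k is the smallest one with
    Gap(k) >= Gapmax - s.e.(Gapmax).

    Attributes
    ----------
    n_clusters_ : int
    labels_ : ndarray
    gap_ : ndarray (k_max,), gap value per candidate k
    gap_se_ : ndarray (k_max,), reference-simulation s.e. per k
    """

    def __init__(
        self,
        k_max: int = 10,
        b_reference: int = 100,
        linkage_method: str = "single",
        random_state: int = 0,
    ):
        self.k_max = k_max
        self.b_reference = b_reference
        self.linkage_method = linkage_method
        self.random_state = random_state

    def _cut(self, X: np.ndarray, k: int) -> np.ndarray:
        Z = linkage(X, method=self.linkage_method)
        return fcluster(Z, t=k, criterion="maxclust")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n <= self.k_max:
            raise ValueError(f"need more than k_max={self.k_max} points, got {n}")
        rng = np.random.default_rng(self.random_state)
        ks = np.arange(1, self.k_max + 1)
        Z = linkage(X, method=self.linkage_method)
        log_w = np.array(
            [np.log(max(_within_dispersion(X, fcluster(Z, t=k, criterion="maxclust")), 1e-300)) for k in ks]
        )
        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_log_w = np.empty((self.b_reference, len(ks)))
        for b in range(self.b_reference):
            R = rng.uniform(lo, hi, size=X.shape)
            Zr = linkage(R, method=self.linkage_method)
            for i, k in enumerate(ks):
                ref_log_w[b, i] = np.log(
                    max(_within_dispersion(R, fcluster(Zr, t=k, criterion="maxclust")), 1e-300)
                )
        gap = ref_log_w.mean(axis=0) - log_w
        se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1 + 1 / self.b_reference)
        k_best = int(np.argmax(gap))
        threshold = gap[k_best] - se[k_best]
        chosen = int(ks[np.flatnonzero(gap >= threshold)[0]])
        self.ks_ = ks
        self.gap_ = gap
        self.gap_se_ = se
        self.n_clusters_ = chosen
        self.labels_ = fcluster(Z, t=chosen, criterion="maxclust") - 1
        return self


def cluster_encoding_weights(
    fits: pd.DataFrame,
    r2_min: float = 0.05,
    k_max: int = 10,
    b_reference: int = 100,
    linkage_method: str = "single",
    seed: int = 0,
) -> tuple[GapStatisticClustering, pd.Index]:
    """Cluster the sum-normalized weight vectors of well-fit neurons.

    Only neurons with R^2 larger than ``r2_min`` enter.  Returns the fitted
    clustering and the index of the neurons that were clustered.
    """
    keep = fits.index[fits["r2"] > r2_min]
    cols = [c for c in fits.columns if c.startswith("nw_") and c != "nw_intercept"]
    if len(keep) <= k_max:
        raise ValueError(
            f"only {len(keep)} neurons pass the R^2 > {r2_min} filter; need > {k_max}"
        )
    model = GapStatisticClustering(
        k_max=k_max,
        b_reference=b_reference,
        linkage_method=linkage_method,
        random_state=seed,
    ).fit(fits.loc[keep, cols].to_numpy())
    return model, keep


# ---------------------------------------------------------------------------
# stepwise selection (task change)

def stepwise_ols(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> tuple[list[str], dict[str, float], float]:
    """Forward-backward stepwise OLS with partial F-tests.

    Candidates enter when their partial F-test p-value (against the current
    model) is below ``alpha_enter``; after each entry, included predictors
    whose p-value rises above ``alpha_remove`` are dropped.  Returns
    (selected names, weights incl. intercept, R^2 of the final model).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    selected: list[str] = []
    remaining = [c for c in X.columns if X[c].std() > 0]

    def rss_of(cols: list[str]) -> tuple[float, np.ndarray]:
        design = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in cols])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            return np.inf, np.zeros(design.shape[1])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.sum((y - design @ beta) ** 2)), beta

    def partial_p(rss_small, rss_big, dof_big):
        if rss_big <= 0:
            return 0.0 if rss_small > rss_big else 1.0
        f = (rss_small - rss_big) / (rss_big / dof_big)
        return float(stats.f.sf(f, 1, dof_big))

    rss_cur, _ = rss_of(selected)
    while True:
        # forward step
        best = None
        for c in remaining:
            rss_new, _ = rss_of(selected + [c])
            if not np.isfinite(rss_new):
                continue
            p = partial_p(rss_cur, rss_new, n - len(selected) - 2)
            if p < alpha_enter and (best is None or p < best[1]):
                best = (c, p, rss_new)
        if best is None:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        rss_cur = best[2]
        # backward step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for c in list(selected):
                others = [s for s in selected if s != c]
                rss_small, _ = rss_of(others)
                p = partial_p(rss_small, rss_cur, n - len(selected) - 1)
                if p > alpha_remove:
                    selected.remove(c)
                    remaining.append(c)
                    rss_cur = rss_small
                    removed = True
                    break
    rss_fin, beta = rss_of(selected)
    tss = float(((y - y.mean()) ** 2).sum())
    weights = {"intercept": float(beta[0])}
    weights.update({c: float(b) for c, b in zip(selected, beta[1:])})
    r2 = 1 - rss_fin / tss if tss > 0 else 0.0
    return selected, weights, r2


def task_change_predictors(trials: pd.DataFrame) -> pd.DataFrame:
    """Predictors for concatenated Go/NoGo (T5) + left/right (L/R) trials.

    category: 1 for category-2 (previous Go) stimuli; go: any Go response
    (Go, GoRight or GoLeft); reward; go_right / go_left: the lateral motor
    responses, 0 for all Go/NoGo-session and missed trials.
    """
    choice = trials["choice"].astype(str)
    return pd.DataFrame(
        {
            "category": (trials["assigned_category"] == GO).astype(float),
            "go": choice.isin(["Go", "GoRight", "GoLeft"]).astype(float),
            "reward": trials["rewarded"].astype(float),
            "go_right": (choice == "GoRight").astype(float),
            "go_left": (choice == "GoLeft").astype(float),
        },
        index=trials.index,
    )


def stepwise_task_change_glm(
    rates: np.ndarray,
    trials: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> pd.DataFrame:
    """Stepwise encoding model across the Go/NoGo -> left/right task change.

    Returns one row per neuron: selected weights (unselected predictors are
    0), max-normalized weights, R^2 and the 'uniquely category-modulated'
    flag (category selected while no motor/choice predictor is).
    """
    X = task_change_predictors(trials)
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    rows = []
    for y in rates:
        sel, weights, r2 = stepwise_ols(X, y, alpha_enter, alpha_remove)
        full = {c: weights.get(c, 0.0) for c in X.columns}
        if sel:
            norm = normalize_weights({c: full[c] for c in sel} or full, mode="max")
        else:
            norm = {}
        rows.append(
            {
                **{f"w_{k}": v for k, v in full.items()},
                "intercept": weights["intercept"],
                "r2": r2,
                **{f"nw_{k}": norm.get(k, 0.0) for k in X.columns},
                "selected": ",".join(sel),
                "uniquely_category": ("category" in sel)
                and not ({"go", "go_right", "go_left"} & set(sel)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variance partitioning with shuffled predictors

def _cv_r2(X: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    pred = np.empty_like(y)
    for train, test in kf.split(X):
        design = np.column_stack([np.ones(len(train)), X[train]])
        beta, _, _, _ = np.linalg.lstsq(design, y[train], rcond=None)
        pred[test] = beta[0] + X[test] @ beta[1:]
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1 - ss_res / ss_tot if ss_tot > 0 else 0.0


def variance_partition(
    rates: np.ndarray,
    predictors: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    n_folds: int = 10,
    n_shuffles: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Cross-validated cvR^2 and delta R^2 per predictor group and neuron.

    cvR^2(g): predictive performance of the model with every predictor
    *except* group g trial-shuffled (its maximum predictive power).
    delta R^2(g): full-model R^2 minus the R^2 of the model with group g
    shuffled (its unique contribution).  Shuffles permute trial labels of
    the targeted columns jointly within a group, averaged over
    ``n_shuffles`` permutations.  Constant predictors get 0 for both.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if groups is None:
        groups = {c: [c] for c in predictors.columns}
    cols = list(predictors.columns)
    Xfull = predictors.to_numpy(dtype=float)
    constant = {g for g, members in groups.items() if all(predictors[m].std() == 0 for m in members)}

    rows = []
    for y in rates:
        full_r2 = _cv_r2(Xfull, y, n_folds, rng)
        rec = {"full_r2": full_r2}
        for g, members in groups.items():
            if g in constant:
                rec[f"cvr2_{g}"] = 0.0
                rec[f"dr2_{g}"] = 0.0
                continue
            keep_idx = [cols.index(m) for m in members]
            other_groups = [m for og, ms in groups.items() if og != g for m in ms]
            cv_scores, d_scores = [], []
            for _ in range(n_shuffles):
                # all others shuffled -> maximum predictive power of g
                Xa = Xfull.copy()
                for og, ms in groups.items():
                    if og == g:
                        continue
                    perm = rng.permutation(len(Xa))
                    for m in ms:
                        Xa[:, cols.index(m)] = Xfull[perm, cols.index(m)]
                cv_scores.append(_cv_r2(Xa, y, n_folds, rng))
                # only g shuffled -> unique contribution
                Xb = Xfull.copy()
                perm = rng.permutation(len(Xb))
                for m in members:
                    Xb[:, cols.index(m)] = Xfull[perm, cols.index(m)]
                d_scores.append(full_r2 - _cv_r2(Xb, y, n_folds, rng))
            rec[f"cvr2_{g}"] = float(np.mean(cv_scores))
            rec[f"dr2_{g}"] = float(np.mean(d_scores))
        rows.append(rec)
    return pd.DataFrame(rows)
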
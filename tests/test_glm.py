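import numpy as np
import pandas as pd
import pytest

from catlearn.glm import (
    GapStatisticClustering,
    TrialGLM,
    cluster_encoding_weights,
    fit_trial_glm,
    normalize_weights,
    stepwise_ols,
    stepwise_task_change_glm,
    task_change_predictors,
    variance_partition,
)


def _random_predictors(n, rng):
    return pd.DataFrame(
        {
            "category": rng.integers(0, 2, n).astype(float),
            "choice": rng.integers(0, 2, n).astype(float),
            "reward": rng.integers(0, 2, n).astype(float),
            "speed": rng.normal(size=n),
        }
    )


class TestTrialGLM:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = _random_predictors(100, rng)
        y = 2.0 * X["category"]
        m = TrialGLM().fit(X, y)
        assert m.coef_[0] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(m.coef_[1:], 0, atol=1e-10)
        assert m.r2_ == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.normal(size=(60, 4))
            y = rng.normal(size=60)
            m = TrialGLM().fit(pd.DataFrame(X, columns=list("abcd")), y)
            D = np.column_stack([np.ones(60), X])
            beta = np.linalg.solve(D.T @ D, D.T @ y)
            assert np.allclose(np.r_[m.intercept_, m.coef_], beta, atol=1e-10)

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = _random_predictors(200, rng)
        y = 1.5 * X["category"] + 0.5 * X["speed"] + rng.normal(0, 0.5, 200)
        m = TrialGLM().fit(X, y)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(m.coef_, sm_fit.params[1:], atol=1e-8)
        assert m.r2_ == pytest.approx(sm_fit.rsquared, abs=1e-10)
        # partial F-test on one regressor equals the squared-t test
        assert np.allclose(m.f_pvalues_, sm_fit.pvalues[1:], atol=1e-8)

    def test_planted_weight_recovery_over_seeds(self):
        true = np.array([1.5, 0.8, 0.3, 0.1])
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = _random_predictors(400, rng)
            y = 1.0 + X.to_numpy() @ true + rng.normal(0, 0.5, 400)
            m = TrialGLM().fit(X, y)
            errs.append(np.abs(m.coef_ - true))
        assert np.all(np.median(errs, axis=0) <= 0.2)

    def test_pure_noise_type_one_rate_calibrated(self):
        hits = np.zeros(4)
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = _random_predictors(100, rng)
            y = rng.normal(size=100)
            m = TrialGLM().fit(X, y)
            hits += m.f_pvalues_ < 0.05
        assert np.all(hits / n_seeds < 0.11)
        assert np.all(hits / n_seeds > 0.005)

    def test_constant_predictor_rejected(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="constant"):
            TrialGLM().fit(X, np.arange(50.0))

    def test_collinear_design_names_predictors(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
        with pytest.raises(ValueError, match="collinear"):
            TrialGLM().fit(X, rng.normal(size=50))

    def test_fit_trial_glm_returns_per_neuron_rows(self):
        rng = np.random.default_rng(4)
        X = _random_predictors(120, rng)
        rates = np.vstack([2 * X["category"] + rng.normal(0, 0.3, 120) for _ in range(5)])
        fits = fit_trial_glm(rates, X)
        assert len(fits) == 5
        assert (fits["sig_category"]).all()
        # sum-normalized absolute weights (incl. intercept) sum to 1
        nw = fits[[c for c in fits.columns if c.startswith("nw_")]]
        assert np.allclose(np.abs(nw).sum(axis=1), 1.0)


class TestNormalizeWeights:
    def test_sum_mode_worked_example(self):
        w = {"intercept": 1.0, "cat": 2.0, "choice": -1.0, "reward": 0.0, "speed": 1.0}
        out = normalize_weights(w, mode="sum")
        assert out["cat"] == pytest.approx(0.4)

    def test_single_nonzero_weight_normalizes_to_unit(self):
        out = normalize_weights({"intercept": 0.0, "cat": -3.0}, mode="sum")
        assert out["cat"] == pytest.approx(-1.0)

    def test_max_mode_largest_weight_is_one(self):
        out = normalize_weights({"a": 0.5, "b": 2.5, "c": -1.0}, mode="max")
        assert max(out.values()) == pytest.approx(1.0)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError):
            normalize_weights({"a": 0.0}, mode="sum")


class TestGapClustering:
    def test_three_archetypes_recovered_with_high_purity(self):
        rng = np.random.default_rng(5)
        centers = np.eye(3)
        X = np.vstack([c + rng.normal(0, 0.05, (40, 3)) for c in centers])
        truth = np.repeat([0, 1, 2], 40)
        m = GapStatisticClustering(k_max=8, b_reference=60, random_state=0).fit(X)
        assert m.n_clusters_ == 3
        purity = sum(
            np.bincount(truth[m.labels_ == k]).max() for k in range(3)
        ) / len(X)
        assert purity > 0.95

    def test_single_blob_gives_k_one(self):
        X = np.random.default_rng(6).normal(0, 1, (80, 3))
        m = GapStatisticClustering(k_max=8, b_reference=60, random_state=0).fit(X)
        assert m.n_clusters_ == 1

    def test_k_invariant_to_common_rescaling_and_seed_reproducible(self):
        rng = np.random.default_rng(7)
        X = np.vstack([c + rng.normal(0, 0.05, (30, 3)) for c in np.eye(3)])
        a = GapStatisticClustering(k_max=6, b_reference=40, random_state=1).fit(X)
        b = GapStatisticClustering(k_max=6, b_reference=40, random_state=1).fit(10 * X)
        assert a.n_clusters_ == b.n_clusters_
        assert np.array_equal(a.labels_, b.labels_)

    def test_nine_archetype_preset_recovered(self):
        # archetype layout mirrors functional cell classes: single-parameter
        # clusters plus mixed combinations
        rng = np.random.default_rng(8)
        eye = np.eye(4)
        mixes = [
            (eye[0] + eye[1]) / 2,
            (eye[1] + eye[2]) / 2,
            (eye[0] + eye[2]) / 2,
            (eye[0] + eye[3]) / 2,
            (eye[0] + eye[1] + eye[2]) / 3,
        ]
        centers = np.vstack([eye, mixes])
        X = np.vstack([c + rng.normal(0, 0.03, (25, 4)) for c in centers])
        m = GapStatisticClustering(k_max=14, b_reference=40, random_state=2).fit(X)
        assert m.n_clusters_ == 9

    def test_r2_filter_applied(self):
        rng = np.random.default_rng(9)
        fits = pd.DataFrame(
            {
                "r2": np.r_[np.full(40, 0.5), np.full(100, 0.01)],
                "nw_category": rng.normal(size=140),
                "nw_choice": rng.normal(size=140),
                "nw_intercept": rng.normal(size=140),
            }
        )
        model, kept = cluster_encoding_weights(fits, k_max=10, b_reference=20, seed=0)
        assert len(kept) == 40
        with pytest.raises(ValueError, match="filter"):
            cluster_encoding_weights(fits.iloc[45:], k_max=10, b_reference=20)


def _task_change_trials(n_t5=150, n_lr=150, seed=0, p_miss=0.15):
    """Concatenated Go/NoGo (T5) + left/right sessions with known structure."""
    rng = np.random.default_rng(seed)
    cat5 = rng.integers(0, 2, n_t5)
    go5 = np.where(rng.random(n_t5) < 0.85, cat5, 1 - cat5)  # mostly correct
    t5 = pd.DataFrame(
        {
            "assigned_category": np.where(cat5 == 1, "Go", "NoGo"),
            "choice": np.where(go5 == 1, "Go", "NoGo"),
            "rewarded": (cat5 == 1) & (go5 == 1),
        }
    )
    catlr = rng.integers(0, 2, n_lr)
    miss = rng.random(n_lr) < p_miss
    correct = rng.random(n_lr) < 0.8
    resp = np.where(catlr == 1, "GoRight", "GoLeft")
    wrong = np.where(catlr == 1, "GoLeft", "GoRight")
    choice = np.where(miss, "Miss", np.where(correct, resp, wrong))
    lr = pd.DataFrame(
        {
            "assigned_category": np.where(catlr == 1, "Go", "NoGo"),
            "choice": choice,
            "rewarded": ~miss & correct,
        }
    )
    return pd.concat([t5, lr], ignore_index=True)


class TestStepwise:
    def test_category_only_neuron_selects_category(self):
        trials = _task_change_trials(seed=1)
        X = task_change_predictors(trials)
        rng = np.random.default_rng(1)
        y = 1.0 + 1.5 * X["category"] + rng.normal(0, 0.3, len(X))
        fits = stepwise_task_change_glm(y.to_numpy()[None, :], trials)
        assert fits["uniquely_category"][0]
        assert fits["w_go"][0] == 0.0

    def test_lick_driven_neuron_selects_motor_not_category(self):
        trials = _task_change_trials(seed=2)
        X = task_change_predictors(trials)
        rng = np.random.default_rng(2)
        y = 1.0 + 1.2 * X["go"] + rng.normal(0, 0.3, len(X))
        fits = stepwise_task_change_glm(y.to_numpy()[None, :], trials)
        sel = set(fits["selected"][0].split(","))
        assert sel & {"go", "go_right", "go_left"}
        assert not fits["uniquely_category"][0]

    def test_go_right_left_zero_for_t5_trials(self):
        trials = _task_change_trials(seed=3)
        X = task_change_predictors(trials)
        assert (X["go_right"].iloc[:150] == 0).all()
        assert (X["go_left"].iloc[:150] == 0).all()
        # missed L/R trials carry no motor predictor
        miss = trials["choice"] == "Miss"
        assert (X.loc[miss, ["go", "go_right", "go_left"]] == 0).all().all()

    def test_planted_category_fraction_recovered(self):
        n_neurons, frac = 100, 0.05
        found = []
        for seed in range(5):
            trials = _task_change_trials(seed=seed)
            X = task_change_predictors(trials)
            rng = np.random.default_rng(seed)
            rates = np.empty((n_neurons, len(X)))
            is_cat = np.arange(n_neurons) < int(frac * n_neurons)
            for i in range(n_neurons):
                drive = 1.0 + (1.5 * X["category"] if is_cat[i] else 0.0)
                rates[i] = drive + rng.normal(0, 0.4, len(X))
            fits = stepwise_task_change_glm(rates, trials)
            found.append(fits["uniquely_category"].mean())
        assert 0.03 <= np.mean(found) <= 0.07

    def test_type_one_rate_within_band(self):
        """A single pure-noise candidate enters in ~alpha of seeds."""
        n_seeds = 400
        admitted = 0
        rng_master = np.random.default_rng(99)
        base = pd.DataFrame(
            {
                "signal": np.tile([0.0, 1.0], 100),
            }
        )
        for _ in range(n_seeds):
            rng = np.random.default_rng(rng_master.integers(2**31))
            X = base.copy()
            X["noise_pred"] = rng.normal(size=200)
            y = 2.0 * X["signal"] + rng.normal(0, 0.5, 200)
            sel, _, _ = stepwise_ols(X, y)
            admitted += "noise_pred" in sel
        assert 0.02 <= admitted / n_seeds <= 0.08


@pytest.fixture(scope="module")
def preds():
    rng = np.random.default_rng(10)
    n = 300
    return pd.DataFrame(
        {
            "category": rng.integers(0, 2, n).astype(float),
            "pupil": rng.normal(size=n),
        }
    )


class TestVariancePartition:

    def test_category_driven_neuron(self, preds):
        rng = np.random.default_rng(11)
        y = 1.5 * preds["category"] + rng.normal(0, 0.4, len(preds))
        vp = variance_partition(y.to_numpy()[None, :], preds, n_shuffles=5, seed=0)
        assert vp["dr2_category"][0] == pytest.approx(vp["full_r2"][0], abs=0.08)
        assert abs(vp["dr2_pupil"][0]) < 0.05

    def test_pupil_driven_neuron(self, preds):
        rng = np.random.default_rng(12)
        y = 1.0 * preds["pupil"] + rng.normal(0, 0.4, len(preds))
        vp = variance_partition(y.to_numpy()[None, :], preds, n_shuffles=5, seed=1)
        assert vp["cvr2_pupil"][0] > 0.5
        assert abs(vp["dr2_category"][0]) < 0.05

    def test_correlated_predictors_share_variance(self):
        rng = np.random.default_rng(13)
        n = 300
        shared = rng.normal(size=n)
        preds = pd.DataFrame({"a": shared, "b": shared.copy()})
        y = shared + rng.normal(0, 0.3, n)
        vp = variance_partition(y[None, :], preds, n_shuffles=5, seed=2)
        assert vp["cvr2_a"][0] > 0.5 and vp["cvr2_b"][0] > 0.5
        assert abs(vp["dr2_a"][0]) < 0.05 and abs(vp["dr2_b"][0]) < 0.05

    def test_constant_predictor_zeroed(self, preds):
        p = preds.copy()
        p["flat"] = 1.0
        y = np.random.default_rng(14).normal(size=len(p))
        vp = variance_partition(y[None, :], p, n_shuffles=3, seed=3)
        assert vp["cvr2_flat"][0] == 0.0
        assert vp["dr2_flat"][0] == 0.0

    def test_irrelevant_predictor_dr2_centered_at_zero(self, preds):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=len(preds))
            vp = variance_partition(y[None, :], preds, n_shuffles=3, seed=seed)
            vals.append(vp["dr2_category"][0])
        assert abs(np.mean(vals)) < 0.02
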
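import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catlearn.selectivity import (
    approximate_category_selectivity,
    classify_selective,
    compute_cti,
    default_templates,
    fit_timecourse_templates,
    fraction_selective,
    population_overlap,
)
from catlearn.stimuli import GO, NOGO
from tests.conftest import ideal_category_rates


def brute_force_cti(rates, labels):
    """Independent pair-enumeration oracle for the category-tuning index."""
    within, across = [], []
    for i, j in itertools.combinations(range(len(rates)), 2):
        if labels[i] == "boundary" or labels[j] == "boundary":
            continue
        d = abs(rates[i] - rates[j])
        (within if labels[i] == labels[j] else across).append(d)
    w, a = np.mean(within), np.mean(across)
    return 0.0 if a + w == 0 else (a - w) / (a + w)


class TestCTI:
    def test_ideal_category_cell_has_cti_one(self, ori_rule):
        assert compute_cti(ideal_category_rates(ori_rule), ori_rule) == 1.0

    def test_uniform_cell_has_cti_zero(self, ori_rule):
        assert compute_cti(np.full(36, 2.7), ori_rule) == 0.0

    def test_single_responsive_stimulus_gives_zero(self, ori_rule):
        rates = np.zeros(36)
        rates[ori_rule.go_ids()[0]] = 1.0
        # within = 17/306 equals across = 18/324 exactly
        assert compute_cti(rates, ori_rule) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_vectors(self, ori_rule):
        rng = np.random.default_rng(0)
        labels = ori_rule.labels()
        for _ in range(200):
            rates = rng.exponential(1.0, 36)
            assert compute_cti(rates, ori_rule) == pytest.approx(
                brute_force_cti(rates, labels), abs=1e-12
            )

    @given(scale=st.floats(0.01, 100.0), data=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_positive_rescaling(self, ori_rule, scale, data):
        rates = np.random.default_rng(data).exponential(1.0, 36)
        a = compute_cti(rates, ori_rule)
        b = compute_cti(scale * rates, ori_rule)
        assert a == pytest.approx(b, abs=1e-9)
        assert -1.0 <= a <= 1.0

    def test_invariant_to_within_category_relabeling(self, ori_rule):
        rng = np.random.default_rng(1)
        rates = rng.exponential(1.0, 36)
        base = compute_cti(rates, ori_rule)
        perm = rates.copy()
        go = ori_rule.go_ids()
        perm[go] = perm[rng.permutation(go)]
        assert compute_cti(perm, ori_rule) == pytest.approx(base, abs=1e-12)

    def test_too_few_stimuli_per_category_rejected(self, ori_rule):
        rates = np.full(36, np.nan)
        rates[ori_rule.go_ids()[:5]] = 1.0
        rates[ori_rule.nogo_ids()[0]] = 0.0
        with pytest.raises(ValueError, match=">=2"):
            compute_cti(rates, ori_rule)


class TestApproximateSelectivity:
    @pytest.mark.parametrize(
        "go_mean, nogo_mean, expected", [(2.0, 0.0, 1.0), (1.3, 1.3, 0.0), (3.0, 1.0, 0.5)]
    )
    def test_contrast_index(self, go_mean, nogo_mean, expected):
        rates = np.array([go_mean] * 10 + [nogo_mean] * 10)
        is_go = np.array([True] * 10 + [False] * 10)
        assert approximate_category_selectivity(rates, is_go) == pytest.approx(expected)

    def test_all_silent_gives_zero(self):
        assert approximate_category_selectivity(np.zeros(8), np.arange(8) < 4) == 0.0


class TestClassification:
    def test_cti_exactly_at_threshold_not_selective(self):
        out = classify_selective(np.array([0.1, 0.100001]), np.ones(2), np.zeros(2))
        assert not out["selective"][0]
        assert out["selective"][1]

    def test_preference_by_rate_difference_and_antisymmetry(self):
        out = classify_selective(np.array([0.5, 0.5]), np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        assert list(out["preferred_category"]) == [GO, NOGO]
        swapped = classify_selective(np.array([0.5, 0.5]), np.array([1.0, 2.0]), np.array([2.0, 1.0]))
        assert list(swapped["preferred_category"]) == [NOGO, GO]

    def test_exact_tie_preference_undefined(self):
        out = classify_selective(np.array([0.5]), np.array([1.0]), np.array([1.0]))
        assert out["preferred_category"][0] is None

    def test_selective_fraction_decreases_with_threshold(self, ori_rule, trained_session):
        from catlearn.simulate import SimConfig
        from catlearn.simulate.neurons import simulate_neurons

        cfg = SimConfig(n_neurons=300, seed=6)
        rates, _ = simulate_neurons(trained_session, cfg, rule=ori_rule)
        stim_rates = _per_stimulus_means(rates, trained_session)
        ctis = np.array([compute_cti(r, ori_rule) for r in stim_rates])
        fracs = [(ctis > th).mean() for th in (0.07, 0.1, 0.15, 0.20)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[-1]


def _per_stimulus_means(rates, trials):
    stim_ids = trials["stimulus_id"].to_numpy()
    out = np.full((rates.shape[0], 36), np.nan)
    for sid in np.unique(stim_ids):
        out[:, sid] = rates[:, stim_ids == sid].mean(axis=1)
    return out


class TestFractionSelective:
    def test_simple_proportion(self):
        flags = np.zeros(200, dtype=bool)
        flags[:20] = True
        out = fraction_selective(flags, np.repeat("A", 200))
        assert out["A"] == pytest.approx(0.10)

    def test_untuned_population_near_zero_false_positives(self, ori_rule, trained_session):
        from catlearn.simulate import SimConfig
        from catlearn.simulate.neurons import simulate_neurons

        cfg = SimConfig(n_neurons=500, fractions={}, seed=7)
        rates, _ = simulate_neurons(trained_session, cfg, rule=ori_rule)
        ctis = np.array([compute_cti(r, ori_rule) for r in _per_stimulus_means(rates, trained_session)])
        assert (ctis > 0.1).mean() < 0.01

    def test_planted_fraction_recovered(self, ori_rule, trained_session):
        from catlearn.simulate import SimConfig
        from catlearn.simulate.neurons import simulate_neurons

        cfg = SimConfig(
            n_neurons=500,
            fractions={"category_go": 0.1},
            selectivity_amplitude=2.0,
            noise_scale=0.1,
            seed=8,
        )
        rates, _ = simulate_neurons(trained_session, cfg, rule=ori_rule)
        ctis = np.array([compute_cti(r, ori_rule) for r in _per_stimulus_means(rates, trained_session)])
        assert 0.08 <= (ctis > 0.1).mean() <= 0.12


class TestPopulationOverlap:
    def test_full_population_overlap(self):
        ids = np.arange(50)
        obs, null95 = population_overlap(ids, ids, 50, n_shuffles=200, seed=0)
        assert obs == 50
        assert null95 == 50

    def test_independent_sets_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(1)
        obs_list = []
        for seed in range(100):
            a = rng.choice(1000, 50, replace=False)
            b = rng.choice(1000, 50, replace=False)
            obs, null95 = population_overlap(a, b, 1000, n_shuffles=100, seed=seed)
            obs_list.append(obs)
        assert np.mean(obs_list) == pytest.approx(2.5, abs=0.7)  # |A||B|/N

    def test_disjoint_planted_sets_below_null(self):
        obs, null95 = population_overlap(np.arange(50), np.arange(50, 100), 1000, seed=2)
        assert obs == 0
        assert obs < null95

    def test_true_overlap_detected_in_most_seeds(self):
        # planted overlap of 20 of 50 in 1000 neurons; null 95th pct ~ 6
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            shared = rng.choice(1000, 20, replace=False)
            rest = np.setdiff1d(np.arange(1000), shared)
            a = np.concatenate([shared, rng.choice(rest, 30, replace=False)])
            b = np.concatenate([shared, rng.choice(rest, 30, replace=False)])
            obs, null95 = population_overlap(a, b, 1000, n_shuffles=200, seed=seed)
            hits += obs > null95
        assert hits >= 38  # >= 95% of seeds


class TestTemplates:
    def test_template_shape_constraints(self):
        t = default_templates()
        for vec in (t.adhoc, t.rule1, t.rule2):
            assert vec[0] == 0.0
            assert vec.max() == 1.0
            assert np.all((0 <= vec) & (vec <= 1))

    def test_exact_template_recovered(self):
        t = default_templates()
        out = fit_timecourse_templates(t.rule1[None, :])
        assert out["w_rule1"][0] == pytest.approx(1.0, abs=1e-9)
        assert out["w_adhoc"][0] == pytest.approx(0.0, abs=1e-9)
        assert out["assigned_template"][0] == "rule1"

    def test_noisy_choice_template_weight_recovered(self):
        t = default_templates()
        w_hat = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vec = 0.5 * t.adhoc + rng.normal(0, 0.05, 8)
            w_hat.append(fit_timecourse_templates(vec[None, :])["w_adhoc"][0])
        assert 0.4 <= np.median(w_hat) <= 0.6

    def test_template_assignment_confusion_matrix(self, series):
        from catlearn.selectivity import selectivity_timecourse

        sessions, gt = series
        tc = selectivity_timecourse(sessions)
        sign = np.where(tc.sum(axis=1) >= 0, 1.0, -1.0)
        fits = fit_timecourse_templates(tc * sign[:, None])
        truth = gt["template"].to_numpy()
        for cls in ("adhoc", "rule1", "rule2"):
            mask = truth == cls
            assert (fits["assigned_template"][mask] == cls).mean() > 0.8

    def test_collinear_templates_rejected(self):
        from catlearn.selectivity import TimeCourseTemplates

        bad = TimeCourseTemplates(
            adhoc=np.ones(8), rule1=np.ones(8) * 0.5, rule2=np.linspace(0, 1, 8)
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_timecourse_templates(np.zeros((1, 8)), templates=bad)
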
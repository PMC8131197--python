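"""Planted neural populations keyed to task variables.

Each simulated neuron belongs to one ground-truth class (Go-preferring
category, NoGo-preferring category, choice, reward, mixed, or untuned) and
its trial-wise mean inferred spike rate is a linear function of the trial's
task variables plus noise, rectified at zero.  Category drive always follows
the currently active rule; a neuron's rule identity lives in its selectivity
template, so after a rule switch the selectivity of rule-1 category neurons
fades while rule-2 neurons acquire selectivity for the new categories —
matching how measured selectivity develops across the learning series.

The default noise is rectified Gaussian; an exponential mode draws each rate
from an exponential distribution whose mean is the linear predictor, for
consistency checks of the exponential-likelihood decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..selectivity import TimeCourseTemplates, default_templates
from ..stimuli import GO, CategoryRule
from .behavior import simulate_behavior

_DEFAULT_FRACTIONS = {
    "category_go": 0.10,
    "category_nogo": 0.05,
    "category_go_rule2": 0.05,
    "category_nogo_rule2": 0.03,
    "choice": 0.10,
    "reward": 0.05,
    "mixed": 0.05,
}

_CLASS_NAMES = tuple(_DEFAULT_FRACTIONS) + ("untuned",)


@dataclass
class SimConfig:
    """Parameters of the neural population simulator.

    Fractions give the share of each ground-truth class; the remainder is
    untuned.  ``selectivity_amplitude`` is the rate difference (a.u./s) an
    ideally driven neuron shows between its preferred and non-preferred
    condition; ``noise_scale`` is the trial-to-trial rate sd.
    """

    n_neurons: int = 200
    fractions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    selectivity_amplitude: float = 1.0
    baseline: float = 1.0
    noise_scale: float = 0.25
    noise_model: str = "rectified_gaussian"  # or "exponential"
    speed_weight: float = 0.0
    n_trials: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(self.fractions.values()) > 1 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        unknown = set(self.fractions) - set(_CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown ground-truth classes: {sorted(unknown)}")
        if self.noise_model not in ("rectified_gaussian", "exponential"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = {k: int(round(v * config.n_neurons)) for k, v in config.fractions.items()}
    while sum(counts.values()) > config.n_neurons:
        k = max(counts, key=counts.get)
        counts[k] -= 1
    labels = sum(([k] * n for k, n in counts.items()), [])
    labels += ["untuned"] * (config.n_neurons - len(labels))
    labels = np.array(labels)
    rng.shuffle(labels)
    return labels


def build_ground_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One record per neuron: class, true weights, rule reference, template."""
    config.validate()
    labels = _assign_classes(config, rng)
    a = config.selectivity_amplitude
    rows = []
    for i, lab in enumerate(labels):
        w = {"w_category": 0.0, "w_choice": 0.0, "w_reward": 0.0, "w_speed": config.speed_weight}
        rule_ref = 0  # 0 = no category weight
        template = "none"
        if lab == "category_go":
            w["w_category"], rule_ref, template = a, 1, "rule1"
        elif lab == "category_nogo":
            w["w_category"], rule_ref, template = -a, 1, "rule1"
        elif lab == "category_go_rule2":
            w["w_category"], rule_ref, template = a, 2, "rule2"
        elif lab == "category_nogo_rule2":
            w["w_category"], rule_ref, template = -a, 2, "rule2"
        elif lab == "choice":
            w["w_choice"], template = a, "adhoc"
        elif lab == "reward":
            w["w_reward"], template = a, "adhoc"
        elif lab == "mixed":
            w["w_category"], w["w_choice"] = 0.6 * a, 0.6 * a
            rule_ref, template = 1, "rule1"
        rows.append({"neuron": i, "class": lab, "rule": rule_ref, "template": template, **w})
    return pd.DataFrame(rows)


def trial_predictors(
    trials: pd.DataFrame,
    category_rule: CategoryRule | None = None,
) -> pd.DataFrame:
    """Binary/continuous task predictors per trial.

    category: 1 for Go-category stimuli (0 NoGo); boundary stimuli take the
    category they were assigned on that presentation.  choice: 1 Go lick;
    reward: 1 rewarded; speed: standardized running speed.
    """
    if category_rule is None:
        cat = (trials["assigned_category"] == GO).astype(float)
    else:
        labels = category_rule.labels()
        stim_cat = labels[trials["stimulus_id"].to_numpy()]
        cat = np.where(
            stim_cat == "boundary",
            (trials["assigned_category"] == GO).to_numpy(),
            stim_cat == GO,
        ).astype(float)
    speed = trials["running_speed"].to_numpy(dtype=float)
    s_sd = speed.std()
    return pd.DataFrame(
        {
            "category": np.asarray(cat, dtype=float),
            "choice": (trials["choice"] == GO).to_numpy().astype(float),
            "reward": trials["rewarded"].to_numpy().astype(float),
            "speed": (speed - speed.mean()) / (s_sd if s_sd > 0 else 1.0),
        },
        index=trials.index,
    )


def _rates_from_drive(drive: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "exponential":
        return rng.exponential(np.clip(drive, 1e-6, None))
    return np.clip(drive + rng.normal(scale=config.noise_scale, size=drive.shape) if config.noise_scale > 0 else drive, 0.0, None)


def simulate_neurons(
    trials: pd.DataFrame,
    config: SimConfig,
    ground_truth: pd.DataFrame | None = None,
    rule: CategoryRule | None = None,
    template_scale: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate trial-wise rates (neurons x trials) for one session.

    ``template_scale`` maps template name -> multiplier in [0, 1] applied to
    the selectivity weights (used by the learning series); omitted names
    default to 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if ground_truth is None:
        ground_truth = build_ground_truth(config, rng)
    scale = {"none": 1.0, "adhoc": 1.0, "rule1": 1.0, "rule2": 1.0}
    if template_scale:
        scale.update(template_scale)

    x = trial_predictors(trials, category_rule=rule)
    n_trials = len(trials)
    rates = np.empty((len(ground_truth), n_trials))
    for i, row in enumerate(ground_truth.itertuples(index=False)):
        s = scale[row.template]
        drive = (
            config.baseline
            + s * row.w_category * x["category"].to_numpy()
            + s * row.w_choice * x["choice"].to_numpy()
            + s * row.w_reward * x["reward"].to_numpy()
            + row.w_speed * x["speed"].to_numpy()
        )
        rates[i] = _rates_from_drive(drive, config, rng)
    return rates, ground_truth


@dataclass
class StageSpec:
    """One imaging time point of the learning series."""

    timepoint: str
    rule: CategoryRule
    target_dprime: float
    n_per_category: int | None = None
    stimulus_ids: np.ndarray | None = None
    n_trials: int | None = None


@dataclass
class Session:
    """One simulated imaging session: behavior plus trial-wise rates."""

    timepoint: str
    rule: CategoryRule
    trials: pd.DataFrame
    rates: np.ndarray
    neuron_ids: np.ndarray


def stage_stimulus_subset(rule: CategoryRule, n_per_category: int) -> np.ndarray:
    """Pick the n most boundary-distant stimuli per category.

    Training stages introduce stimuli from the extremes of the relevant
    feature inward; ties across irrelevant-feature levels are broken by
    cycling through those levels so subsets span the irrelevant dimension.
    """
    dist = rule.signed_distance()
    labels = rule.labels()
    irr = rule.space.feature_values(rule.irrelevant_feature)
    irr_rank = np.searchsorted(np.unique(irr), irr)
    picks = []
    for cat in (GO, "NoGo"):
        ids = np.flatnonzero(labels == cat)
        order = sorted(ids, key=lambda i: (-abs(dist[i]), irr_rank[i] % 3, irr_rank[i]))
        picks.extend(order[:n_per_category])
    return np.sort(np.array(picks, dtype=int))


def simulate_learning_series(
    stages: list[StageSpec],
    config: SimConfig,
    templates: TimeCourseTemplates | None = None,
) -> tuple[list[Session], pd.DataFrame]:
    """Simulate the whole learning series with a shared, tracked population.

    Neuron identity is preserved across sessions; each neuron's selectivity
    amplitude follows its assigned characteristic time course (ad hoc
    choice/reward, gradual rule 1, late rule 2) evaluated at the stage index.
    """
    if not stages:
        raise ValueError("at least one stage required")
    templates = templates if templates is not None else default_templates(len(stages))
    if len(templates.adhoc) != len(stages):
        raise ValueError("template length must match number of stages")
    rng = np.random.default_rng(config.seed)
    ground_truth = build_ground_truth(config, rng)
    sessions = []
    for t_idx, stage in enumerate(stages):
        stimulus_ids = stage.stimulus_ids
        if stimulus_ids is None and stage.n_per_category is not None:
            stimulus_ids = stage_stimulus_subset(stage.rule, stage.n_per_category)
        if stimulus_ids is not None and len(stimulus_ids) == 0:
            raise ValueError(f"stage {stage.timepoint} has zero stimuli")
        trials = simulate_behavior(
            stage.rule,
            stage.target_dprime,
            stage.n_trials or config.n_trials,
            rng,
            stimulus_ids=stimulus_ids,
            timepoint=stage.timepoint,
        )
        scale = {
            "adhoc": float(templates.adhoc[t_idx]),
            "rule1": float(templates.rule1[t_idx]),
            "rule2": float(templates.rule2[t_idx]),
        }
        # category drive follows the *active* rule; a neuron's rule identity
        # lives in its template (rule-1 selectivity fades after the switch,
        # rule-2 selectivity only appears during rule-2 training)
        rates, _ = simulate_neurons(
            trials,
            config,
            ground_truth=ground_truth,
            rule=stage.rule,
            template_scale=scale,
            rng=rng,
        )
        sessions.append(
            Session(
                timepoint=stage.timepoint,
                rule=stage.rule,
                trials=trials,
                rates=rates,
                neuron_ids=ground_truth["neuron"].to_numpy(),
            )
        )
    return sessions, ground_truth


def default_learning_schedule(
    rule1: CategoryRule,
    rule2: CategoryRule,
    dprimes: tuple[float, ...] = (0.0, 1.8, 2.0, 2.2, 2.5, 1.8, 2.2, 2.5),
    n_trials: int | None = None,
) -> list[StageSpec]:
    """Eight-stage schedule T1-T8 with a rule switch after T5.

    T1 presents the full grid to a naive animal (d' 0); training stages grow
    the per-category stimulus count (1, 3, 9, 18) for rule 1, then the
    feature roles swap and rule 2 repeats the progression (1, 9, 18).
    """
    n_per_cat = (None, 1, 3, 9, None, 1, 9, None)  # None = full grid
    rules = (rule1,) * 5 + (rule2,) * 3
    return [
        StageSpec(
            timepoint=f"T{i + 1}",
            rule=rules[i],
            target_dprime=dprimes[i],
            n_per_category=n_per_cat[i],
            n_trials=n_trials,
        )
        for i in range(8)
    ]
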
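"""Stimulus spaces and category rules for the visual categorization task.

The task presents drifting sinusoidal gratings drawn from a factorial grid of
orientations and spatial frequencies.  A *rule* makes one of the two features
category-defining: stimuli whose relevant-feature value lies on one side of a
boundary (45 degrees for the orientation rule, 0.043 cyc/deg for the spatial
frequency rule) form the Go category, the others the NoGo category.  In the
dense stimulus space, grid levels may fall exactly on the boundary; such
stimuli belong to both categories and are labelled ``"boundary"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

# Feature lists used in the study.
STANDARD_ORIENTATIONS = [0.0, 15.0, 30.0, 60.0, 75.0, 90.0]
STANDARD_SFS = [0.023, 0.027, 0.033, 0.06, 0.1, 0.25]
DENSE_ORIENTATIONS = [15.0, 30.0, 37.5, 45.0, 52.5, 60.0, 75.0]
DENSE_SFS = [0.027, 0.033, 0.036, 0.043, 0.052, 0.06, 0.1]

ORIENTATION_BOUNDARY = 45.0
SF_BOUNDARY = 0.043

Feature = Literal["orientation", "spatial_frequency"]

GO = "Go"
NOGO = "NoGo"
BOUNDARY = "boundary"


@dataclass(frozen=True)
class StimulusSpace:
    """Full factorial grid of gratings.

    Stimulus ids are assigned row-major (orientation-major) and are stable:
    id = i_orientation * n_sfs + i_sf.
    """

    orientations: tuple[float, ...]
    spatial_frequencies: tuple[float, ...]

    @property
    def n_stimuli(self) -> int:
        return len(self.orientations) * len(self.spatial_frequencies)

    def table(self) -> pd.DataFrame:
        """One row per stimulus: id, orientation, spatial_frequency."""
        oris = np.repeat(self.orientations, len(self.spatial_frequencies))
        sfs = np.tile(self.spatial_frequencies, len(self.orientations))
        return pd.DataFrame(
            {
                "stimulus_id": np.arange(self.n_stimuli),
                "orientation": oris,
                "spatial_frequency": sfs,
            }
        )

    def feature_values(self, feature: Feature) -> np.ndarray:
        """Per-stimulus value of one feature, indexed by stimulus id."""
        return self.table()[_column(feature)].to_numpy()


def _column(feature: Feature) -> str:
    if feature not in ("orientation", "spatial_frequency"):
        raise ValueError(f"unknown feature {feature!r}")
    return feature


def _plural(feature: Feature) -> str:
    return "orientations" if feature == "orientation" else "spatial_frequencies"


def build_stimulus_grid(orientations, spatial_frequencies) -> StimulusSpace:
    """Build the factorial orientation x spatial-frequency grid.

    Both lists must be non-empty, strictly increasing and duplicate-free.
    """
    for name, values in (
        ("orientations", orientations),
        ("spatial_frequencies", spatial_frequencies),
    ):
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError(f"{name} must be strictly increasing without duplicates")
    return StimulusSpace(
        orientations=tuple(float(v) for v in orientations),
        spatial_frequencies=tuple(float(v) for v in spatial_frequencies),
    )


@dataclass(frozen=True)
class CategoryRule:
    """A category boundary on one stimulus feature.

    ``label_map`` maps stimulus id -> {"Go", "NoGo", "boundary"}.  The Go side
    is the side *above* the boundary by default (``go_side="above"``).
    """

    space: StimulusSpace
    relevant_feature: Feature
    boundary: float
    go_side: Literal["above", "below"] = "above"
    dense_mode: bool = False
    label_map: dict[int, str] = field(default_factory=dict)

    @property
    def irrelevant_feature(self) -> Feature:
        return (
            "spatial_frequency"
            if self.relevant_feature == "orientation"
            else "orientation"
        )

    def labels(self) -> np.ndarray:
        """Per-stimulus category labels ordered by stimulus id."""
        return np.array([self.label_map[i] for i in range(self.space.n_stimuli)])

    def go_ids(self) -> np.ndarray:
        return np.flatnonzero(self.labels() == GO)

    def nogo_ids(self) -> np.ndarray:
        return np.flatnonzero(self.labels() == NOGO)

    def boundary_ids(self) -> np.ndarray:
        return np.flatnonzero(self.labels() == BOUNDARY)

    def signed_distance(self) -> np.ndarray:
        """Signed rank distance of each stimulus to the boundary, in [-1, 1].

        Computed on the rank index of the relevant-feature level rather than
        raw units, because the grid is linear in orientation but geometric in
        spatial frequency; positive values lie on the Go side.
        """
        levels = np.asarray(getattr(self.space, _plural(self.relevant_feature)))
        ranks = np.arange(len(levels), dtype=float)
        below = levels < self.boundary
        above = levels > self.boundary
        if not below.any() or not above.any():
            raise ValueError("boundary must lie strictly inside the feature range")
        # boundary rank sits midway between the flanking levels (or exactly on
        # a level present in the dense grid)
        on = np.isclose(levels, self.boundary)
        if on.any():
            b_rank = float(ranks[on][0])
        else:
            b_rank = (ranks[below][-1] + ranks[above][0]) / 2.0
        dist = ranks - b_rank
        dist /= np.abs(dist).max()
        if self.go_side == "below":
            dist = -dist
        values = self.space.feature_values(self.relevant_feature)
        level_of = {v: i for i, v in enumerate(levels)}
        return np.array([dist[level_of[v]] for v in values])


def assign_categories(
    space: StimulusSpace,
    relevant_feature: Feature,
    boundary: float,
    dense_mode: bool = False,
    go_side: Literal["above", "below"] = "above",
) -> CategoryRule:
    """Label every stimulus Go / NoGo (or boundary) under a category rule.

    In ``dense_mode`` stimuli whose relevant-feature value equals the boundary
    are labelled ``"boundary"`` (they belong to both categories and are
    rewarded on half of the Go responses).  Outside dense mode a boundary that
    coincides with a grid level would make labelling ambiguous and is an
    error.
    """
    _column(relevant_feature)
    levels = np.asarray(getattr(space, _plural(relevant_feature)), dtype=float)
    if not (levels.min() < boundary < levels.max()):
        raise ValueError(
            f"boundary {boundary} must lie strictly inside the "
            f"{relevant_feature} range [{levels.min()}, {levels.max()}]"
        )
    values = space.feature_values(relevant_feature)
    on_boundary = np.isclose(values, boundary)
    if on_boundary.any() and not dense_mode:
        raise ValueError(
            f"boundary {boundary} coincides with a {relevant_feature} grid level; "
            "labelling is ambiguous outside dense mode"
        )
    if go_side == "above":
        go = values > boundary
    else:
        go = values < boundary
    labels = np.where(on_boundary, BOUNDARY, np.where(go, GO, NOGO))
    label_map = {int(i): str(lab) for i, lab in enumerate(labels)}
    return CategoryRule(
        space=space,
        relevant_feature=relevant_feature,
        boundary=float(boundary),
        go_side=go_side,
        dense_mode=dense_mode,
        label_map=label_map,
    )


def standard_grid() -> StimulusSpace:
    """The 6 x 6 training grid (36 gratings)."""
    return build_stimulus_grid(STANDARD_ORIENTATIONS, STANDARD_SFS)


def dense_grid() -> StimulusSpace:
    """The 7 x 7 dense grid (49 gratings) with levels on the boundary."""
    return build_stimulus_grid(DENSE_ORIENTATIONS, DENSE_SFS)


def orientation_rule(space: StimulusSpace | None = None, dense_mode: bool = False) -> CategoryRule:
    space = space if space is not None else (dense_grid() if dense_mode else standard_grid())
    return assign_categories(space, "orientation", ORIENTATION_BOUNDARY, dense_mode=dense_mode)


def sf_rule(space: StimulusSpace | None = None, dense_mode: bool = False) -> CategoryRule:
    space = space if space is not None else (dense_grid() if dense_mode else standard_grid())
    return assign_categories(space, "spatial_frequency", SF_BOUNDARY, dense_mode=dense_mode)
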
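"""Composite colon-damage scores for the DSS-colitis model.

The macroscopic total damage score (0-15) combines stool consistency
(0-3), an ulcer score (0-3), colon length and weight scored by percent
change relative to the control-group mean (0-4 points each), and the
presence of fecal blood (0/1).  A total of 0 means no inflammation.

The microscopic total damage score (3-11) sums five histology subscores:
goblet-cell depletion (0/1), crypt abscesses (0/1), and three graded
features scored 1-3 (mucosal architecture destruction, muscle thickening,
immune-cell infiltration).

Scores are computed from expert-recorded raw observations; no image
analysis happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# Percent-change bins for colon length/weight, as (upper_edge, points).
# Intervals: [0, 5] -> 0, (5, 15) -> 1, [15, 25) -> 2, [25, 35) -> 3,
# [35, inf) -> 4.  An exact 35% change scores 4 (the severe bin wins where
# the printed rule table overlaps).  Centralised here so the convention can
# be changed in one place.
PERCENT_CHANGE_BINS: tuple[tuple[float, int], ...] = (
    (5.0, 0),
    (15.0, 1),
    (25.0, 2),
    (35.0, 3),
)

_STOOL_RANGE = (0, 3)
_ULCER_RANGE = (0, 3)


@dataclass(frozen=True)
class ControlReference:
    """Control-group mean colon length (cm) and weight (g).

    Percent changes for the macroscopic score are computed relative to
    these means.
    """

    control_mean_length: float
    control_mean_weight: float

    def __post_init__(self) -> None:
        if self.control_mean_length <= 0 or self.control_mean_weight <= 0:
            raise ValueError("control reference means must be > 0")


@dataclass(frozen=True)
class HistologySubscores:
    """Expert-assigned histology subscores for one colon section."""

    goblet_depletion: int
    crypt_abscesses: int
    mucosal_architecture: int
    muscle_thickening: int
    immune_infiltration: int

    def __post_init__(self) -> None:
        _check_range("goblet_depletion", self.goblet_depletion, 0, 1)
        _check_range("crypt_abscesses", self.crypt_abscesses, 0, 1)
        _check_range("mucosal_architecture", self.mucosal_architecture, 1, 3)
        _check_range("muscle_thickening", self.muscle_thickening, 1, 3)
        _check_range("immune_infiltration", self.immune_infiltration, 1, 3)


@dataclass(frozen=True)
class MacroscopicResult:
    """Component points and total macroscopic damage score (0-15)."""

    stool_points: int
    ulcer_points: int
    length_points: int
    weight_points: int
    blood_points: int

    @property
    def total(self) -> int:
        return (
            self.stool_points
            + self.ulcer_points
            + self.length_points
            + self.weight_points
            + self.blood_points
        )


def _check_range(name: str, value, lo: int, hi: int) -> None:
    if not float(value).is_integer() or not lo <= int(value) <= hi:
        raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


def percent_change_points(value: float, control_mean: float) -> int:
    """Points (0-4) for the percent change of a colon parameter vs control.

    The change is the absolute percent deviation
    ``100 * |value - control_mean| / control_mean`` (the colon shortens
    under DSS but its weight may rise, so direction is ignored), mapped
    through :data:`PERCENT_CHANGE_BINS`.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    if value < 0:
        raise ValueError("measured value must be >= 0")
    change = 100.0 * abs(value - control_mean) / control_mean
    if change <= PERCENT_CHANGE_BINS[0][0]:
        return PERCENT_CHANGE_BINS[0][1]
    for upper, points in PERCENT_CHANGE_BINS[1:]:
        if change < upper:
            return points
    return PERCENT_CHANGE_BINS[-1][1] + 1


def macroscopic_total(record, ref: ControlReference) -> MacroscopicResult:
    """Total macroscopic damage score for one animal.

    ``record`` needs attributes ``stool_score``, ``ulcer_score``,
    ``fecal_blood``, ``colon_length`` and ``colon_weight`` (an
    :class:`~colitistats.cohort.AnimalRecord`, a namespace, or a pandas
    row via :func:`score_cohort`).  Ulcer counts above 3 clamp to 3, since
    the score is capped there.
    """
    _check_range("stool_score", record.stool_score, *_STOOL_RANGE)
    ulcers = int(record.ulcer_score)
    if ulcers < 0:
        raise ValueError(f"ulcer_score must be >= 0, got {ulcers}")
    ulcers = min(ulcers, _ULCER_RANGE[1])
    _check_range("fecal_blood", record.fecal_blood, 0, 1)
    return MacroscopicResult(
        stool_points=int(record.stool_score),
        ulcer_points=ulcers,
        length_points=percent_change_points(
            record.colon_length, ref.control_mean_length
        ),
        weight_points=percent_change_points(
            record.colon_weight, ref.control_mean_weight
        ),
        blood_points=int(record.fecal_blood),
    )


def microscopic_total(h: HistologySubscores) -> int:
    """Microscopic total damage score: sum of the five subscores (3-11)."""
    return (
        h.goblet_depletion
        + h.crypt_abscesses
        + h.mucosal_architecture
        + h.muscle_thickening
        + h.immune_infiltration
    )


def score_cohort(frame: pd.DataFrame, ref: ControlReference) -> pd.DataFrame:
    """Per-animal score table with component columns.

    Takes a cohort frame (one row per animal, columns named as in
    :class:`~colitistats.cohort.AnimalRecord`) and returns it with
    ``stool_points .. blood_points`` and ``macroscopic_total`` appended;
    ``microscopic_total`` is added where all histology columns are present.
    """
    out = frame.copy()
    results = [macroscopic_total(row, ref) for row in frame.itertuples(index=False)]
    for comp in ("stool_points", "ulcer_points", "length_points",
                 "weight_points", "blood_points"):
        out[comp] = [getattr(r, comp) for r in results]
    out["macroscopic_total"] = [r.total for r in results]

    histo_cols = ["goblet_depletion", "crypt_abscesses", "mucosal_architecture",
                  "muscle_thickening", "immune_infiltration"]
    if all(c in frame.columns for c in histo_cols):
        out["microscopic_total"] = [
            microscopic_total(HistologySubscores(*(int(row[c]) for c in histo_cols)))
            for _, row in frame.iterrows()
        ]
    return out
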
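"""Study designs for synthetic DSS-colitis cohorts.

A :class:`StudyDesign` describes a multi-arm animal experiment the way the
downstream analysis assumes it: per-group normal distributions for the
continuous endpoints, per-group categorical distributions for the ordinal
scores, and an optional additive synergy shift applied to the combination
arm's endpoint means on top of whatever the single-drug arms contribute.

The shipped default mirrors a five-arm design — healthy control, DSS
colitis, DSS plus each monotherapy, and DSS plus the combination — with 8
animals per group.  Designs round-trip through YAML/JSON config files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

#: continuous endpoints the generator draws, with units
CONTINUOUS_ENDPOINTS = (
    "body_weight_pct",   # final body-weight change day 0 -> 7, percent
    "colon_length_cm",
    "colon_weight_g",
    "mpo_mU_per_g",
)

#: ordinal endpoints with their admissible values
ORDINAL_LEVELS: dict[str, tuple[int, ...]] = {
    "stool_score": (0, 1, 2, 3),
    "ulcer_score": (0, 1, 2, 3),
    "fecal_blood": (0, 1),
    "goblet_depletion": (0, 1),
    "crypt_abscesses": (0, 1),
    "mucosal_architecture": (1, 2, 3),
    "muscle_thickening": (1, 2, 3),
    "immune_infiltration": (1, 2, 3),
}


@dataclass
class StudyDesign:
    """Parameters of a simulated multi-arm colitis experiment.

    Parameters
    ----------
    groups
        Ordered unique group labels; the first is the healthy control.
    n_per_group
        Animals per group (>= 2).
    endpoint_params
        ``{group: {endpoint: (mean, sd)}}`` for the continuous endpoints.
    ordinal_probs
        ``{group: {endpoint: [p_level0, ...]}}``; probabilities are in the
        order of :data:`ORDINAL_LEVELS` values and must sum to 1.
    combination_group
        Label of the combination arm that receives ``synergy_shift``.
    synergy_shift
        ``{endpoint: additive shift}`` applied to the combination group's
        mean beyond the sum of single-drug effects already encoded in
        ``endpoint_params``; empty means no synergy.
    baseline_weight_mean, baseline_weight_sd
        Day-0 body weight distribution in grams (adult mice, 22-26 g).
    seed
        Default RNG seed for :func:`~colitistats.cohort.generate_cohort`.
    """

    groups: tuple[str, ...]
    n_per_group: int
    endpoint_params: dict[str, dict[str, tuple[float, float]]]
    ordinal_probs: dict[str, dict[str, list[float]]]
    combination_group: str | None = None
    synergy_shift: dict[str, float] = field(default_factory=dict)
    baseline_weight_mean: float = 24.0
    baseline_weight_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.validate()

    def validate(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.baseline_weight_sd < 0:
            raise ValueError("baseline_weight_sd must be >= 0")
        for g in self.groups:
            if g not in self.endpoint_params:
                raise ValueError(f"endpoint_params missing group {g!r}")
            for ep in CONTINUOUS_ENDPOINTS:
                if ep not in self.endpoint_params[g]:
                    raise ValueError(f"group {g!r} missing endpoint {ep!r}")
                mean, sd = self.endpoint_params[g][ep]
                if sd < 0:
                    raise ValueError(f"SD for {g!r}/{ep!r} must be >= 0, got {sd}")
            if g not in self.ordinal_probs:
                raise ValueError(f"ordinal_probs missing group {g!r}")
            for ep, levels in ORDINAL_LEVELS.items():
                probs = self.ordinal_probs[g].get(ep)
                if probs is None:
                    raise ValueError(f"group {g!r} missing ordinal probs for {ep!r}")
                p = np.asarray(probs, dtype=float)
                if p.size != len(levels):
                    raise ValueError(
                        f"{g!r}/{ep!r} needs {len(levels)} probabilities, got {p.size}"
                    )
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                    raise ValueError(
                        f"probabilities for {g!r}/{ep!r} must be >= 0 and sum to 1"
                    )
        if self.combination_group is not None and (
            self.combination_group not in self.groups
        ):
            raise ValueError(
                f"combination_group {self.combination_group!r} not among groups"
            )
        for ep in self.synergy_shift:
            if ep not in CONTINUOUS_ENDPOINTS:
                raise ValueError(f"synergy_shift names unknown endpoint {ep!r}")

    def effective_mean(self, group: str, endpoint: str) -> float:
        """Group mean including the synergy shift on the combination arm."""
        mean = self.endpoint_params[group][endpoint][0]
        if group == self.combination_group:
            mean += self.synergy_shift.get(endpoint, 0.0)
        return mean

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["endpoint_params"] = {
            g: {ep: list(v) for ep, v in eps.items()}
            for g, eps in self.endpoint_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["endpoint_params"] = {
            g: {ep: tuple(v) for ep, v in eps.items()}
            for g, eps in d["endpoint_params"].items()
        }
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "StudyDesign":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def _healthy_ordinals() -> dict[str, list[float]]:
    return {
        "stool_score": [0.90, 0.10, 0.0, 0.0],
        "ulcer_score": [0.95, 0.05, 0.0, 0.0],
        "fecal_blood": [0.98, 0.02],
        "goblet_depletion": [0.95, 0.05],
        "crypt_abscesses": [0.95, 0.05],
        "mucosal_architecture": [0.90, 0.08, 0.02],
        "muscle_thickening": [0.90, 0.08, 0.02],
        "immune_infiltration": [0.90, 0.08, 0.02],
    }


def _colitis_ordinals() -> dict[str, list[float]]:
    return {
        "stool_score": [0.05, 0.15, 0.40, 0.40],
        "ulcer_score": [0.10, 0.30, 0.40, 0.20],
        "fecal_blood": [0.30, 0.70],
        "goblet_depletion": [0.20, 0.80],
        "crypt_abscesses": [0.40, 0.60],
        "mucosal_architecture": [0.10, 0.40, 0.50],
        "muscle_thickening": [0.20, 0.50, 0.30],
        "immune_infiltration": [0.10, 0.40, 0.50],
    }


def default_design(
    n_per_group: int = 8,
    synergy_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> StudyDesign:
    """Five-arm default design: control, DSS, two monotherapies, combination.

    Endpoint means reflect a severe DSS episode — roughly 20% colon
    shortening, ~25% colon-weight gain, a large MPO rise and ~15% body
    weight loss versus healthy controls — with the drug arms close to the
    DSS arm (the study situation where monotherapies have little effect and
    synergy, if present, is injected via ``synergy_shift``).
    """
    healthy = {
        "body_weight_pct": (3.0, 2.0),
        "colon_length_cm": (8.0, 0.5),
        "colon_weight_g": (0.25, 0.03),
        "mpo_mU_per_g": (2.0, 1.0),
    }
    colitis = {
        "body_weight_pct": (-15.0, 4.0),
        "colon_length_cm": (6.4, 0.5),
        "colon_weight_g": (0.32, 0.04),
        "mpo_mU_per_g": (15.0, 4.0),
    }
    mono = {
        "body_weight_pct": (-14.0, 4.0),
        "colon_length_cm": (6.5, 0.5),
        "colon_weight_g": (0.31, 0.04),
        "mpo_mU_per_g": (13.0, 4.0),
    }
    combo = {
        "body_weight_pct": (-13.5, 4.0),
        "colon_length_cm": (6.55, 0.5),
        "colon_weight_g": (0.31, 0.04),
        "mpo_mU_per_g": (12.0, 4.0),
    }
    groups = ("control", "DSS", "DSS+A", "DSS+B", "DSS+A+B")
    return StudyDesign(
        groups=groups,
        n_per_group=n_per_group,
        endpoint_params={
            "control": dict(healthy),
            "DSS": dict(colitis),
            "DSS+A": dict(mono),
            "DSS+B": dict(mono),
            "DSS+A+B": dict(combo),
        },
        ordinal_probs={
            g: (_healthy_ordinals() if g == "control" else _colitis_ordinals())
            for g in groups
        },
        combination_group="DSS+A+B",
        synergy_shift=dict(synergy_shift or {}),
        seed=seed,
    )
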
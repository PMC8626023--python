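"""Synthetic cohort generation and cohort file I/O.

Generates per-animal records with the statistical structure the analysis
assumes: normally distributed continuous endpoints, categorically
distributed ordinal subscores, a geometric body-weight trajectory over
days 0-7 reaching the group's configured final percent change, and raw MPO
plate-reader kinetics synthesised to be consistent with each animal's
target MPO activity (the inverse of the forward assay computation, so the
round trip is exact at zero noise).

Cohorts serialise to a flat CSV, one row per animal, body weights as
day-indexed columns ``bw_d0..bw_d7`` and kinetics as replicate/timepoint
columns ``abs_r{1..3}_t{0,30,60}``; plate data can also be written in long
format (animal_id, replicate, time_s, absorbance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONTINUOUS_ENDPOINTS, ORDINAL_LEVELS, StudyDesign
from .mpo import (
    DEFAULT_HOMOGENATE_CONCENTRATION,
    DEFAULT_SUPERNATANT_VOLUME,
    DEFAULT_TIMEPOINTS,
    MPOKinetics,
    StandardCurve,
)
from .scoring import HistologySubscores

N_DAYS = 8  # body weights recorded on days 0..7

#: standard curve used when synthesising kinetics for a cohort.  The slope
#: is chosen so that tissue activities in the simulated range (roughly
#: 2-15 mU/g, i.e. 4e-4 to 3e-3 mU in the well) give absorbance rates of
#: ~0.02-0.16 abs/min — well above plate-reader noise, as a usable assay
#: must be.
DEFAULT_CURVE = StandardCurve(slope=50.0, intercept=0.0)

#: absorbance noise (SD, absorbance units) added to synthetic plate reads
DEFAULT_ABSORBANCE_NOISE = 0.002

_BASELINE_ABSORBANCE = 0.05


@dataclass
class AnimalRecord:
    """One animal's raw endpoints, as recorded on day 7."""

    animal_id: str
    group: str
    body_weight_series: np.ndarray  # grams on days 0..7
    colon_length: float             # cm
    colon_weight: float             # g, with fecal content
    stool_score: int                # 0-3
    ulcer_score: int                # 0-3
    fecal_blood: int                # 0/1
    histology: HistologySubscores | None = None
    mpo_kinetics: MPOKinetics | None = None
    mpo_activity: float | None = None  # mU per g wet tissue

    def __post_init__(self) -> None:
        self.body_weight_series = np.asarray(self.body_weight_series, dtype=float)
        if np.any(self.body_weight_series <= 0):
            raise ValueError("body weights must be positive")
        if self.colon_length <= 0:
            raise ValueError("colon_length must be > 0")
        if self.colon_weight <= 0:
            raise ValueError("colon_weight must be > 0")
        for name, hi in (("stool_score", 3), ("ulcer_score", 3), ("fecal_blood", 1)):
            v = getattr(self, name)
            if not 0 <= int(v) <= hi:
                raise ValueError(f"{name} must be in [0, {hi}], got {v}")

    @property
    def body_weight_pct(self) -> float:
        """Percent body-weight change from day 0 to the final day."""
        bw = self.body_weight_series
        return 100.0 * (bw[-1] - bw[0]) / bw[0]


def synthesize_mpo_kinetics(
    target_activity: float,
    tissue_mass: float = 0.030,
    curve: StandardCurve = DEFAULT_CURVE,
    noise_sd: float = 0.0,
    seed: int | None = None,
    homogenate_concentration: float = DEFAULT_HOMOGENATE_CONCENTRATION,
    supernatant_volume_in_well: float = DEFAULT_SUPERNATANT_VOLUME,
) -> MPOKinetics:
    """Plate-reader kinetics whose forward computation recovers a target.

    Inverts the assay arithmetic: the per-gram target is converted to the
    activity present in the well (``target * concentration * volume``),
    mapped through the standard curve to an absorbance rate, and laid out
    as a linear triplicate trace at 0/30/60 s starting from a small
    baseline absorbance.  Gaussian noise of SD ``noise_sd`` (absorbance
    units) is added per reading; with ``noise_sd = 0`` the round trip
    through :func:`colitistats.mpo.mpo_activity` is exact to numerical
    tolerance.
    """
    if target_activity < 0:
        raise ValueError("target_activity must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    activity_in_well = (
        target_activity * homogenate_concentration * supernatant_volume_in_well
    )
    rate_per_min = curve.rate_for_activity(activity_in_well)
    rate_per_s = rate_per_min / 60.0
    t = np.asarray(DEFAULT_TIMEPOINTS)
    trace = _BASELINE_ABSORBANCE + rate_per_s * t
    absorbance = np.tile(trace, (3, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=absorbance.shape)
    absorbance = np.clip(absorbance, 0.0, None)
    return MPOKinetics(
        absorbance=absorbance,
        timepoints_s=tuple(t),
        tissue_mass=tissue_mass,
        homogenate_concentration=homogenate_concentration,
        supernatant_volume_in_well=supernatant_volume_in_well,
    )


def generate_cohort(
    design: StudyDesign,
    seed: int | None = None,
    curve: StandardCurve = DEFAULT_CURVE,
    absorbance_noise_sd: float = DEFAULT_ABSORBANCE_NOISE,
    include_kinetics: bool = True,
) -> list[AnimalRecord]:
    """Draw a full cohort from a study design.

    Exactly ``design.n_per_group`` records per group; continuous endpoints
    are normal draws from the configured (mean, SD) — the combination
    group's means include ``synergy_shift`` — and ordinal endpoints are
    categorical draws.  Fully reproducible given the seed (``design.seed``
    when ``seed`` is None).

    Body-weight trajectories place a normal baseline weight at day 0 and
    apply a constant daily multiplicative trend so that day 7 realises the
    animal's drawn final percent change.

    ``include_kinetics=False`` skips synthesising per-animal plate reads,
    which is convenient for very large simulated cohorts.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    records: list[AnimalRecord] = []
    days = np.arange(N_DAYS)
    n = design.n_per_group
    for group in design.groups:
        cont = {
            ep: rng.normal(design.effective_mean(group, ep),
                           design.endpoint_params[group][ep][1], size=n)
            for ep in CONTINUOUS_ENDPOINTS
        }
        ordin = {
            ep: rng.choice(ORDINAL_LEVELS[ep], size=n,
                           p=design.ordinal_probs[group][ep])
            for ep in ORDINAL_LEVELS
        }
        baseline = np.clip(
            rng.normal(design.baseline_weight_mean, design.baseline_weight_sd,
                       size=n),
            18.0, 30.0,
        )
        for i in range(n):
            final_frac = max(1.0 + cont["body_weight_pct"][i] / 100.0, 0.5)
            daily = final_frac ** (1.0 / (N_DAYS - 1))
            bw = baseline[i] * daily ** days

            mpo_target = max(float(cont["mpo_mU_per_g"][i]), 0.0)
            kinetics = None
            if include_kinetics:
                kin_seed = int(rng.integers(0, 2**31 - 1))
                kinetics = synthesize_mpo_kinetics(
                    mpo_target,
                    curve=curve,
                    noise_sd=absorbance_noise_sd,
                    seed=kin_seed,
                )
            records.append(
                AnimalRecord(
                    animal_id=f"{group}_{i + 1:02d}",
                    group=group,
                    body_weight_series=bw,
                    colon_length=max(float(cont["colon_length_cm"][i]), 1e-6),
                    colon_weight=max(float(cont["colon_weight_g"][i]), 1e-6),
                    stool_score=int(ordin["stool_score"][i]),
                    ulcer_score=int(ordin["ulcer_score"][i]),
                    fecal_blood=int(ordin["fecal_blood"][i]),
                    histology=HistologySubscores(
                        goblet_depletion=int(ordin["goblet_depletion"][i]),
                        crypt_abscesses=int(ordin["crypt_abscesses"][i]),
                        mucosal_architecture=int(ordin["mucosal_architecture"][i]),
                        muscle_thickening=int(ordin["muscle_thickening"][i]),
                        immune_infiltration=int(ordin["immune_infiltration"][i]),
                    ),
                    mpo_kinetics=kinetics,
                    mpo_activity=mpo_target,
                )
            )
    return records


# -- tabular conversion and CSV I/O -----------------------------------------

_KINETIC_COLS = [
    f"abs_r{r + 1}_t{int(t)}" for r in range(3) for t in DEFAULT_TIMEPOINTS
]


def cohort_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Flatten records to one row per animal."""
    rows = []
    for r in records:
        row: dict = {"animal_id": r.animal_id, "group": r.group}
        for d in range(N_DAYS):
            row[f"bw_d{d}"] = r.body_weight_series[d]
        row.update(
            colon_length=r.colon_length,
            colon_weight=r.colon_weight,
            stool_score=r.stool_score,
            ulcer_score=r.ulcer_score,
            fecal_blood=r.fecal_blood,
            mpo_activity=r.mpo_activity,
        )
        if r.histology is not None:
            row.update(
                goblet_depletion=r.histology.goblet_depletion,
                crypt_abscesses=r.histology.crypt_abscesses,
                mucosal_architecture=r.histology.mucosal_architecture,
                muscle_thickening=r.histology.muscle_thickening,
                immune_infiltration=r.histology.immune_infiltration,
            )
        if r.mpo_kinetics is not None:
            flat = r.mpo_kinetics.absorbance.ravel()
            for col, v in zip(_KINETIC_COLS, flat):
                row[col] = v
            row["tissue_mass"] = r.mpo_kinetics.tissue_mass
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[AnimalRecord]:
    """Rebuild records from a flat cohort frame (inverse of cohort_to_frame)."""
    records = []
    histo_cols = ["goblet_depletion", "crypt_abscesses", "mucosal_architecture",
                  "muscle_thickening", "immune_infiltration"]
    for _, row in frame.iterrows():
        histology = None
        if all(c in frame.columns and pd.notna(row[c]) for c in histo_cols):
            histology = HistologySubscores(*(int(row[c]) for c in histo_cols))
        kinetics = None
        if all(c in frame.columns and pd.notna(row[c]) for c in _KINETIC_COLS):
            absorbance = np.array([row[c] for c in _KINETIC_COLS]).reshape(3, 3)
            kinetics = MPOKinetics(
                absorbance=absorbance,
                tissue_mass=float(row.get("tissue_mass", 0.030)),
            )
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                body_weight_series=np.array(
                    [row[f"bw_d{d}"] for d in range(N_DAYS)]
                ),
                colon_length=float(row["colon_length"]),
                colon_weight=float(row["colon_weight"]),
                stool_score=int(row["stool_score"]),
                ulcer_score=int(row["ulcer_score"]),
                fecal_blood=int(row["fecal_blood"]),
                histology=histology,
                mpo_kinetics=kinetics,
                mpo_activity=(
                    float(row["mpo_activity"])
                    if "mpo_activity" in frame.columns and pd.notna(row["mpo_activity"])
                    else None
                ),
            )
        )
    return records


def write_cohort_csv(records: list[AnimalRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def kinetics_long_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Plate data in long format: animal_id, replicate, time_s, absorbance."""
    rows = []
    for r in records:
        if r.mpo_kinetics is None:
            continue
        for rep in range(r.mpo_kinetics.absorbance.shape[0]):
            for t, a in zip(r.mpo_kinetics.timepoints_s,
                            r.mpo_kinetics.absorbance[rep]):
                rows.append(
                    {"animal_id": r.animal_id, "replicate": rep + 1,
                     "time_s": t, "absorbance": a}
                )
    return pd.DataFrame(rows)
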
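"""Myeloperoxidase (MPO) activity from kinetic plate-reader data.

MPO is a neutrophil enzyme whose tissue activity serves as a proxy for
inflammatory cell infiltration.  The assay measures the rate of
O-dianisidine oxidation: absorbance at 450 nm is read in triplicate at 0,
30 and 60 s after the reaction starts.  The absorbance-vs-time slope
(converted to absorbance per minute) is mapped to enzyme units through a
standard curve fitted on purified peroxidase, and the units in the assayed
well are normalised to milliunits per gram of wet tissue.

One unit of MPO converts 1 umol of hydrogen peroxide per minute.  The well
contains ``supernatant_volume_in_well`` mL of a homogenate prepared at
``homogenate_concentration`` grams of tissue per mL, so the grams of tissue
represented in the well are the product of the two; dividing the well
activity by that mass yields the per-gram value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

logger = logging.getLogger(__name__)

#: g wet tissue per mL homogenisation buffer (approx. 30 mg tissue/mL)
DEFAULT_HOMOGENATE_CONCENTRATION = 0.030
#: mL of supernatant pipetted into the assay well (7 uL)
DEFAULT_SUPERNATANT_VOLUME = 0.007

DEFAULT_TIMEPOINTS = (0.0, 30.0, 60.0)


@dataclass
class MPOKinetics:
    """Raw kinetic readings for one tissue sample.

    Parameters
    ----------
    absorbance
        Array of shape (n_replicates, n_timepoints); absorbance at 450 nm.
        The assay design is 3 replicates x 3 timepoints.
    timepoints_s
        Read times in seconds, strictly increasing.
    tissue_mass
        Grams of wet tissue that were homogenised (recorded for
        provenance; the per-gram normalisation uses the homogenate
        concentration, not this mass).
    homogenate_concentration
        g tissue per mL buffer.
    supernatant_volume_in_well
        mL of supernatant assayed per well.
    """

    absorbance: np.ndarray
    timepoints_s: tuple[float, ...] = DEFAULT_TIMEPOINTS
    tissue_mass: float = 0.030
    homogenate_concentration: float = DEFAULT_HOMOGENATE_CONCENTRATION
    supernatant_volume_in_well: float = DEFAULT_SUPERNATANT_VOLUME

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        t = np.asarray(self.timepoints_s, dtype=float)
        if t.size < 2:
            raise ValueError("at least 2 timepoints are required to fit a rate")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.absorbance.shape[1] != t.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} timepoints, "
                f"expected {t.size}"
            )
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance values must be >= 0")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")
        if self.tissue_mass <= 0:
            raise ValueError("tissue_mass must be > 0")
        if self.homogenate_concentration <= 0:
            raise ValueError("homogenate_concentration must be > 0")
        if self.supernatant_volume_in_well <= 0:
            raise ValueError("supernatant_volume_in_well must be > 0")
        self.timepoints_s = tuple(t)


@dataclass
class StandardCurve:
    """Linear calibration: rate (abs/min) = slope * activity (mU) + intercept.

    Fitted on known peroxidase amounts with :func:`fit_standard_curve`, or
    constructed directly when slope and intercept are known.
    """

    slope: float
    intercept: float = 0.0
    calibration_points: tuple[tuple[float, float], ...] = ()
    residual_sd: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be > 0")

    def rate_for_activity(self, activity_mU: float) -> float:
        """Forward prediction: expected rate for a known well activity."""
        return self.slope * activity_mU + self.intercept


def reaction_rate(k: MPOKinetics, aggregate: str = "mean") -> float:
    """Least-squares absorbance slope, in absorbance units per minute.

    Each replicate trace is fitted by ordinary least squares against the
    read times; per-replicate slopes (per second) are converted to per
    minute and aggregated across replicates (mean by default, median
    optionally).  Enzyme activity cannot be negative, so a negative
    aggregate slope clamps to 0 with a log message.
    """
    t = np.asarray(k.timepoints_s)
    # closed-form OLS slope per replicate: cov(t, A) / var(t)
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    slopes_per_s = (k.absorbance - k.absorbance.mean(axis=1, keepdims=True)) @ tc / denom
    slopes_per_min = slopes_per_s * 60.0
    if aggregate == "mean":
        rate = float(np.mean(slopes_per_min))
    elif aggregate == "median":
        rate = float(np.median(slopes_per_min))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}; use 'mean' or 'median'")
    if rate < 0:
        logger.info("negative fitted reaction rate %.4g abs/min clamped to 0", rate)
        return 0.0
    return rate


def fit_standard_curve(points) -> StandardCurve:
    """OLS fit of measured rate against known peroxidase activity.

    Parameters
    ----------
    points
        Iterable of (activity_mU, rate_abs_per_min) calibration pairs;
        at least two distinct activities are required.
    """
    pts = [(float(a), float(r)) for a, r in points]
    if len(pts) < 2:
        raise ValueError("at least 2 calibration points are required")
    activity = np.array([p[0] for p in pts])
    rate = np.array([p[1] for p in pts])
    if np.unique(activity).size < 2:
        raise ValueError("calibration activities are degenerate (all identical)")
    fit = _st.linregress(activity, rate)
    resid = rate - (fit.slope * activity + fit.intercept)
    dof = max(len(pts) - 2, 1)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        calibration_points=tuple(pts),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=float(fit.rvalue**2),
    )


def mpo_activity(k: MPOKinetics, curve: StandardCurve, aggregate: str = "mean") -> float:
    """MPO activity in mU per gram of wet tissue.

    The well activity is ``(reaction_rate - intercept) / slope`` (clamped
    at zero), and the per-gram value divides by the grams of tissue present
    in the assayed supernatant aliquot,
    ``homogenate_concentration * supernatant_volume_in_well``.
    """
    rate = reaction_rate(k, aggregate=aggregate)
    activity_in_well = (rate - curve.intercept) / curve.slope
    if activity_in_well < 0:
        logger.info(
            "negative well activity %.4g mU clamped to 0", activity_in_well
        )
        activity_in_well = 0.0
    grams_in_well = k.homogenate_concentration * k.supernatant_volume_in_well
    return activity_in_well / grams_in_well
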
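"""Full study analysis: summaries, classical tests, bootstrap synergy.

The pipeline mirrors how a preclinical colitis study is reported.  For
each endpoint (macroscopic total score, colon length, colon weight, MPO
activity, body-weight change) it produces group means +/- SEM, a
Shapiro-Wilk normality check per group, one-way ANOVA with
Bonferroni-adjusted pairwise contrasts (each treated group vs control and
vs the DSS arm), and — for every configured monotherapy-vs-combination
contrast — the bootstrap test of the absolute difference in means, which
is the synergy read-out: the combination shows synergy on an endpoint only
if its mean separates from the monotherapy by more than resampling noise.

p-values from the pairwise contrasts are Bonferroni-corrected within each
endpoint's contrast family; no correction is applied across endpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .bootstrap import DEFAULT_ITERATIONS, BootstrapResult, bootstrap_p
from .scoring import ControlReference, score_cohort

logger = logging.getLogger(__name__)

#: endpoints reported by default, in study order
DEFAULT_ENDPOINTS = (
    "body_weight_pct",
    "macroscopic_total",
    "colon_length",
    "colon_weight",
    "mpo_activity",
)

#: significance-star thresholds, most significant first
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Star annotation for a p-value (ns above alpha)."""
    if p >= alpha:
        return "ns"
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "*"


def prepare_endpoints(frame: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Derive analysis endpoints from a raw cohort frame.

    Adds ``body_weight_pct`` (day 0 -> final-day percent change from the
    ``bw_d*`` columns) and the macroscopic score columns, using the
    control group's mean colon length and weight as the percent-change
    reference.
    """
    out = frame.copy()
    bw_cols = sorted(
        (c for c in frame.columns if c.startswith("bw_d")),
        key=lambda c: int(c.removeprefix("bw_d")),
    )
    if bw_cols and "body_weight_pct" not in out.columns:
        out["body_weight_pct"] = (
            100.0 * (frame[bw_cols[-1]] - frame[bw_cols[0]]) / frame[bw_cols[0]]
        )
    if control_group not in set(frame["group"]):
        raise ValueError(f"control group {control_group!r} not present in cohort")
    ctrl = frame[frame["group"] == control_group]
    ref = ControlReference(
        control_mean_length=float(ctrl["colon_length"].mean()),
        control_mean_weight=float(ctrl["colon_weight"].mean()),
    )
    return score_cohort(out, ref)


def _endpoint_values(frame: pd.DataFrame, group: str, endpoint: str) -> np.ndarray:
    if endpoint not in frame.columns:
        raise ValueError(f"endpoint {endpoint!r} absent from cohort")
    if group not in set(frame["group"]):
        raise ValueError(f"unknown group label {group!r}")
    vals = frame.loc[frame["group"] == group, endpoint].to_numpy(dtype=float)
    n_missing = int(np.count_nonzero(~np.isfinite(vals)))
    if n_missing:
        logger.info("excluding %d missing %s values in group %s",
                    n_missing, endpoint, group)
    return vals[np.isfinite(vals)]


def summarize_groups(frame: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Mean, SD, SEM and n per group for one endpoint.

    Missing values are excluded (with a logged count); SEM is SD/sqrt(n).
    """
    if endpoint not in frame.columns or frame[endpoint].dropna().empty:
        raise ValueError(f"endpoint {endpoint!r} absent from all records")
    rows = []
    for group in pd.unique(frame["group"]):
        vals = _endpoint_values(frame, group, endpoint)
        if vals.size < 2:
            raise ValueError(
                f"group {group!r} has {vals.size} usable values for "
                f"{endpoint!r}; >= 2 required"
            )
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {"group": group, "n": int(vals.size), "mean": float(vals.mean()),
             "sd": sd, "sem": sd / np.sqrt(vals.size)}
        )
    return pd.DataFrame(rows)


@dataclass
class ClassicalResults:
    """ANOVA, normality and Bonferroni-adjusted pairwise contrasts."""

    endpoint: str
    anova_f: float
    anova_p: float
    shapiro: dict[str, dict[str, float]]
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_bonferroni, stars


def default_contrasts(
    groups, control_group: str, dss_group: str
) -> list[tuple[str, str]]:
    """Each non-control group vs control, and each treated group vs DSS."""
    contrasts = [(g, control_group) for g in groups if g != control_group]
    contrasts += [
        (g, dss_group) for g in groups if g not in (control_group, dss_group)
    ]
    return contrasts


def run_classical_tests(
    frame: pd.DataFrame,
    endpoint: str,
    alpha: float = 0.05,
    contrasts: list[tuple[str, str]] | None = None,
    control_group: str = "control",
    dss_group: str = "DSS",
) -> ClassicalResults:
    """Shapiro-Wilk per group, one-way ANOVA, Bonferroni pairwise t-tests.

    Normality rejection is a logged warning, not an abort: the analysis
    proceeds parametrically regardless, with the bootstrap contrast as the
    small-sample safeguard.  Pairwise comparisons are restricted to the
    configured contrast set; adjusted p is ``min(1, m * p)`` over the m
    contrasts actually run.
    """
    groups = list(pd.unique(frame["group"]))
    samples = {g: _endpoint_values(frame, g, endpoint) for g in groups}
    small = [g for g, v in samples.items() if v.size < 3]
    if len(groups) < 2 or small:
        raise ValueError(
            f"need >= 2 groups with >= 3 animals each for {endpoint!r}; "
            f"too small: {small}"
        )
    if all(np.var(v) == 0 for v in samples.values()):
        raise ValueError("zero within-group variance everywhere; F undefined")

    shapiro: dict[str, dict[str, float]] = {}
    for g, vals in samples.items():
        if np.var(vals) == 0:
            shapiro[g] = {"W": float("nan"), "p": float("nan")}
            continue
        w, p = _st.shapiro(vals)
        shapiro[g] = {"W": float(w), "p": float(p)}
        if p < alpha:
            logger.warning(
                "Shapiro-Wilk rejects normality for %s/%s (p=%.3g); "
                "parametric tests proceed", g, endpoint, p,
            )

    f_stat, anova_p = _st.f_oneway(*samples.values())

    if contrasts is None:
        contrasts = default_contrasts(groups, control_group, dss_group)
    rows = []
    for ga, gb in contrasts:
        if ga not in samples or gb not in samples:
            raise ValueError(f"contrast ({ga!r}, {gb!r}) names an unknown group")
        t, p = _st.ttest_ind(samples[ga], samples[gb])
        rows.append({"group_a": ga, "group_b": gb,
                     "t": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        pairwise["p_bonferroni"] = multipletests(
            pairwise["p_raw"], method="bonferroni"
        )[1]
        pairwise["stars"] = [
            significance_stars(p, alpha) for p in pairwise["p_bonferroni"]
        ]
    return ClassicalResults(
        endpoint=endpoint,
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        shapiro=shapiro,
        pairwise=pairwise,
    )


def assess_synergy(
    frame: pd.DataFrame,
    contrast: tuple[str, str],
    endpoint: str,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    strategy: str = "pooled",
) -> BootstrapResult:
    """Bootstrap test of monotherapy vs combination on one endpoint.

    Extracts the two groups' endpoint values and delegates to
    :func:`colitistats.bootstrap.bootstrap_p`; the result pairs the
    observed absolute difference in means with its bootstrap p-value.
    """
    mono, combo = contrast
    a = _endpoint_values(frame, mono, endpoint)
    b = _endpoint_values(frame, combo, endpoint)
    return bootstrap_p(a, b, n_iterations=n_iterations, seed=seed,
                       strategy=strategy)


@dataclass
class ReportConfig:
    """What the study report covers and how the tests are run."""

    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS
    control_group: str = "control"
    dss_group: str = "DSS"
    synergy_contrasts: tuple[tuple[str, str], ...] = (
        ("DSS+A", "DSS+A+B"),
        ("DSS+B", "DSS+A+B"),
    )
    n_iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    alpha: float = 0.05
    strategy: str = "pooled"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["endpoints"] = list(self.endpoints)
        d["synergy_contrasts"] = [list(c) for c in self.synergy_contrasts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReportConfig":
        d = dict(d)
        if "endpoints" in d:
            d["endpoints"] = tuple(d["endpoints"])
        if "synergy_contrasts" in d:
            d["synergy_contrasts"] = tuple(tuple(c) for c in d["synergy_contrasts"])
        return cls(**d)


@dataclass
class SynergyReport:
    """Per-endpoint summaries, classical tests and bootstrap contrasts."""

    config: ReportConfig
    summaries: dict[str, pd.DataFrame]
    classical: dict[str, ClassicalResults]
    synergy: dict[str, dict[str, BootstrapResult]]  # endpoint -> "mono|combo"

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "summaries": {
                ep: df.to_dict(orient="records") for ep, df in self.summaries.items()
            },
            "classical": {
                ep: {
                    "anova_f": c.anova_f,
                    "anova_p": c.anova_p,
                    "shapiro": c.shapiro,
                    "pairwise": c.pairwise.to_dict(orient="records"),
                }
                for ep, c in self.classical.items()
            },
            "synergy": {
                ep: {label: r.to_dict() for label, r in contrasts.items()}
                for ep, contrasts in self.synergy.items()
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_tables(self, directory) -> None:
        """CSV tables: one summary and one pairwise table per endpoint,
        plus a flat synergy-contrast table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for ep, df in self.summaries.items():
            df.to_csv(directory / f"summary_{ep}.csv", index=False)
        for ep, c in self.classical.items():
            c.pairwise.to_csv(directory / f"pairwise_{ep}.csv", index=False)
        rows = []
        for ep, contrasts in self.synergy.items():
            for label, r in contrasts.items():
                mono, combo = label.split("|")
                rows.append(
                    {"endpoint": ep, "monotherapy": mono, "combination": combo,
                     "observed_diff_means": r.observed_test_stat,
                     "p_bootstrap": r.p_bootstrap,
                     "n_iterations": r.n_iterations,
                     "significant": r.p_bootstrap < self.config.alpha}
                )
        pd.DataFrame(rows).to_csv(directory / "synergy_contrasts.csv", index=False)


def build_report(frame: pd.DataFrame, config: ReportConfig | None = None) -> SynergyReport:
    """Run the whole analysis on a (raw or scored) cohort frame.

    Endpoint columns missing from the frame are derived with
    :func:`prepare_endpoints` first.  Bootstrap seeds are spawned
    deterministically from ``config.seed`` per (endpoint, contrast), so a
    rerun with the same inputs gives byte-identical JSON.
    """
    config = config or ReportConfig()
    if any(ep not in frame.columns for ep in config.endpoints):
        frame = prepare_endpoints(frame, control_group=config.control_group)
    missing = [ep for ep in config.endpoints if ep not in frame.columns]
    if missing:
        raise ValueError(f"endpoints missing from cohort: {missing}")
    groups = set(frame["group"])
    for label in (config.control_group, config.dss_group):
        if label not in groups:
            raise ValueError(f"group {label!r} named in config but absent")
    for mono, combo in config.synergy_contrasts:
        for label in (mono, combo):
            if label not in groups:
                raise ValueError(
                    f"synergy contrast group {label!r} absent from cohort"
                )

    root = np.random.SeedSequence(config.seed)
    seeds = iter(root.generate_state(
        len(config.endpoints) * max(len(config.synergy_contrasts), 1)
    ) % (2**31 - 1))

    summaries, classical, synergy = {}, {}, {}
    for ep in config.endpoints:
        summaries[ep] = summarize_groups(frame, ep)
        classical[ep] = run_classical_tests(
            frame, ep, alpha=config.alpha,
            control_group=config.control_group, dss_group=config.dss_group,
        )
        synergy[ep] = {}
        for mono, combo in config.synergy_contrasts:
            synergy[ep][f"{mono}|{combo}"] = assess_synergy(
                frame, (mono, combo), ep,
                n_iterations=config.n_iterations,
                seed=int(next(seeds)),
                strategy=config.strategy,
            )
    return SynergyReport(config=config, summaries=summaries,
                         classical=classical, synergy=synergy)
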
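"""Synthetic cohort generator: determinism, distributions, MPO round trip."""

import numpy as np
import pandas as pd
import pytest

from colitistats import (
    StudyDesign,
    cohort_to_frame,
    default_design,
    frame_to_cohort,
    generate_cohort,
    kinetics_long_frame,
    mpo_activity,
    read_cohort_csv,
    synthesize_mpo_kinetics,
    write_cohort_csv,
)
from colitistats.cohort import DEFAULT_CURVE
from colitistats.design import CONTINUOUS_ENDPOINTS


def two_group_design(shift=0.0, n=8, seed=0):
    """Minimal monotherapy-vs-combination design for focused simulations."""
    base = default_design()
    params = {
        "mono": dict(base.endpoint_params["DSS+A"]),
        "combo": dict(base.endpoint_params["DSS+A"]),
    }
    probs = {g: base.ordinal_probs["DSS"] for g in ("mono", "combo")}
    return StudyDesign(
        groups=("mono", "combo"),
        n_per_group=n,
        endpoint_params=params,
        ordinal_probs=probs,
        combination_group="combo",
        synergy_shift={"colon_length_cm": shift} if shift else {},
        seed=seed,
    )


class TestDesignValidation:
    def test_default_design_is_valid(self):
        default_design().validate()

    def test_negative_sd_rejected(self):
        d = default_design()
        d.endpoint_params["DSS"]["colon_length_cm"] = (6.4, -0.5)
        with pytest.raises(ValueError, match="SD"):
            d.validate()

    def test_probabilities_must_sum_to_one(self):
        d = default_design()
        d.ordinal_probs["DSS"]["stool_score"] = [0.5, 0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="sum to 1"):
            d.validate()

    def test_duplicate_groups_rejected(self):
        d = default_design()
        with pytest.raises(ValueError, match="unique"):
            StudyDesign(
                groups=("control", "control"),
                n_per_group=4,
                endpoint_params=d.endpoint_params,
                ordinal_probs=d.ordinal_probs,
            )

    def test_small_n_rejected(self):
        d = default_design()
        d.n_per_group = 1
        with pytest.raises(ValueError, match="n_per_group"):
            d.validate()

    def test_config_roundtrip(self, tmp_path):
        d = default_design(n_per_group=6, synergy_shift={"mpo_mU_per_g": -3.0})
        for name in ("design.yaml", "design.json"):
            path = tmp_path / name
            d.save(path)
            loaded = StudyDesign.load(path)
            assert loaded.to_dict() == d.to_dict()


def test_unknown_synergy_endpoint_rejected_at_construction():
    with pytest.raises(ValueError, match="unknown endpoint"):
        default_design(synergy_shift={"typo": 1.0})


class TestGenerateCohort:
    def test_group_sizes_and_unique_ids(self):
        design = default_design(n_per_group=5)
        records = generate_cohort(design, seed=1)
        frame = cohort_to_frame(records)
        assert frame.groupby("group").size().eq(5).all()
        assert frame["animal_id"].is_unique

    def test_same_seed_gives_identical_cohorts(self):
        design = default_design(n_per_group=6)
        f1 = cohort_to_frame(generate_cohort(design, seed=9))
        f2 = cohort_to_frame(generate_cohort(design, seed=9))
        pd.testing.assert_frame_equal(f1, f2)
        assert f1.to_csv(index=False) == f2.to_csv(index=False)

    def test_different_seeds_differ(self):
        design = default_design(n_per_group=6)
        f1 = cohort_to_frame(generate_cohort(design, seed=1))
        f2 = cohort_to_frame(generate_cohort(design, seed=2))
        assert not f1["colon_length"].equals(f2["colon_length"])

    def test_body_weight_trend_is_geometric(self):
        records = generate_cohort(default_design(n_per_group=3), seed=4)
        bw = records[0].body_weight_series
        ratios = bw[1:] / bw[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_ordinal_fields_within_range(self):
        frame = cohort_to_frame(generate_cohort(default_design(), seed=5))
        assert frame["stool_score"].between(0, 3).all()
        assert frame["ulcer_score"].between(0, 3).all()
        assert frame["fecal_blood"].isin([0, 1]).all()
        assert frame["mucosal_architecture"].between(1, 3).all()

    def test_large_cohort_matches_design_distributions(self):
        """Empirical means/SDs track the configured normals within 1%."""
        design = two_group_design(n=10_000)
        records = generate_cohort(design, seed=11, include_kinetics=False)
        frame = cohort_to_frame(records)
        mono = frame[frame["group"] == "mono"]
        col_for = {
            "body_weight_pct": None,  # derived, checked via bw columns below
            "colon_length_cm": "colon_length",
            "colon_weight_g": "colon_weight",
            "mpo_mU_per_g": "mpo_activity",
        }
        for ep in CONTINUOUS_ENDPOINTS:
            col = col_for[ep]
            if col is None:
                vals = 100.0 * (mono["bw_d7"] - mono["bw_d0"]) / mono["bw_d0"]
            else:
                vals = mono[col]
            mean, sd = design.endpoint_params["mono"][ep]
            assert vals.mean() == pytest.approx(mean, rel=0.01)
            assert vals.std(ddof=1) == pytest.approx(sd, rel=0.01)

    def test_parameter_recovery_of_injected_shift(self):
        """A 20% colon-length deficit (vs control) is recovered within 2 SE
        of the replicate-averaged group-mean difference (Monte Carlo)."""
        base = default_design(n_per_group=8)
        true_diff = (base.endpoint_params["control"]["colon_length_cm"][0]
                     - base.endpoint_params["DSS"]["colon_length_cm"][0])
        assert true_diff == pytest.approx(0.20 * 8.0)  # the injected 20% shift
        n_rep, n = 500, 8
        sd = base.endpoint_params["DSS"]["colon_length_cm"][1]
        diffs = np.empty(n_rep)
        for r in range(n_rep):
            frame = cohort_to_frame(
                generate_cohort(base, seed=1000 + r, include_kinetics=False)
            )
            by_group = frame.groupby("group")["colon_length"].mean()
            diffs[r] = by_group["control"] - by_group["DSS"]
        se_one = sd * np.sqrt(2.0 / n)
        assert abs(diffs.mean() - true_diff) <= 2 * se_one / np.sqrt(n_rep)

    def test_synergy_shift_moves_combination_mean(self):
        design = two_group_design(shift=-1.5, n=2000)
        frame = cohort_to_frame(
            generate_cohort(design, seed=3, include_kinetics=False)
        )
        means = frame.groupby("group")["colon_length"].mean()
        assert means["combo"] == pytest.approx(means["mono"] - 1.5, abs=0.1)


class TestSynthesizeMPOKinetics:
    def test_zero_target_zero_noise_is_flat(self):
        k = synthesize_mpo_kinetics(0.0, noise_sd=0.0)
        assert np.ptp(k.absorbance) == 0.0
        assert mpo_activity(k, DEFAULT_CURVE) == 0.0

    def test_exact_round_trip_without_noise(self):
        for target in (0.5, 10.0, 120.0):
            k = synthesize_mpo_kinetics(target, noise_sd=0.0)
            assert mpo_activity(k, DEFAULT_CURVE) == pytest.approx(
                target, rel=1e-9
            )

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match="target_activity"):
            synthesize_mpo_kinetics(-1.0)

    def test_noise_is_reproducible_by_seed(self):
        k1 = synthesize_mpo_kinetics(10.0, noise_sd=0.005, seed=77)
        k2 = synthesize_mpo_kinetics(10.0, noise_sd=0.005, seed=77)
        assert np.array_equal(k1.absorbance, k2.absorbance)

    def test_noisy_round_trip_is_unbiased(self):
        """Mean recovered activity over many seeds stays within 3x the
        propagated SE of the mean (SE of one OLS slope through 3 triplicate
        reads, pushed through the curve and the dilution factor)."""
        target, noise, n_seeds = 10.0, 0.005, 300
        recovered = np.array([
            mpo_activity(
                synthesize_mpo_kinetics(target, noise_sd=noise, seed=s),
                DEFAULT_CURVE,
            )
            for s in range(n_seeds)
        ])
        # var(slope per s) = noise^2 / sum((t - tbar)^2) = noise^2/1800;
        # per-minute x60, averaged over 3 replicates, through curve + dilution
        se_one = (noise * np.sqrt(3600.0 / 1800.0 / 3.0)
                  / (DEFAULT_CURVE.slope * 0.030 * 0.007))
        assert abs(recovered.mean() - target) <= 3 * se_one / np.sqrt(n_seeds)


class TestCohortIO:
    def test_csv_round_trip_preserves_records(self, tmp_path):
        records = generate_cohort(default_design(n_per_group=3), seed=21)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        frame = read_cohort_csv(path)
        back = frame_to_cohort(frame)
        assert len(back) == len(records)
        for orig, rec in zip(records, back):
            assert rec.animal_id == orig.animal_id
            assert rec.group == orig.group
            assert rec.colon_length == pytest.approx(orig.colon_length)
            assert rec.stool_score == orig.stool_score
            assert rec.histology == orig.histology
            np.testing.assert_allclose(
                rec.mpo_kinetics.absorbance, orig.mpo_kinetics.absorbance
            )

    def test_kinetics_long_format(self):
        records = generate_cohort(default_design(n_per_group=2), seed=8)
        long = kinetics_long_frame(records)
        assert set(long.columns) == {"animal_id", "replicate", "time_s",
                                     "absorbance"}
        assert len(long) == len(records) * 9  # 3 replicates x 3 timepoints
        assert sorted(long["time_s"].unique()) == [0.0, 30.0, 60.0]
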
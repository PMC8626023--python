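"""Run the whole study analysis on a synthetic cohort.

Simulates a cohort with a deliberately large combination effect on MPO
activity, then builds the full report: per-endpoint group summaries,
Shapiro-Wilk checks, one-way ANOVA with Bonferroni-adjusted contrasts, and
the bootstrap monotherapy-vs-combination synergy tests.
"""

from colitistats import (
    ReportConfig,
    build_report,
    cohort_to_frame,
    default_design,
    generate_cohort,
)

design = default_design(n_per_group=8, synergy_shift={"mpo_mU_per_g": -9.0})
frame = cohort_to_frame(generate_cohort(design, seed=7))
report = build_report(frame, ReportConfig(seed=7))

print("MPO activity (mU/g), group summaries:")
print(report.summaries["mpo_activity"].round(2).to_string(index=False))

print("\nANOVA p per endpoint:")
for ep, c in report.classical.items():
    print(f"  {ep:18s} p = {c.anova_p:.2e}")

print("\nbootstrap synergy contrasts on MPO activity:")
for label, r in report.synergy["mpo_activity"].items():
    flag = "synergy" if r.p_bootstrap < 0.05 else "no synergy"
    print(f"  {label:16s} |diff means| = {r.observed_test_stat:6.3f}  "
          f"P_bootstrap = {r.p_bootstrap:.4f}  -> {flag}")
print("\nThe injected -9 mU/g shift on the combination arm separates it"
      "\nfrom both monotherapies by more than resampling noise.")
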
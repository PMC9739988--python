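"""Optimal cut-point discovery and Cox survival modelling on a synthetic cohort.

Generates a proportional-hazards cohort whose eTILs distribution has a true
prognostic change-point at 13.2% (hazard 3x higher below it), re-discovers
the threshold by the maximally selected log-rank scan, and fits univariate
and multivariate Cox models.
"""

from tilquant import find_optimal_cutpoint, generate_cohort, kaplan_meier
from tilquant.survival import run_table2_models
from tilquant.synthetic import CohortSpec


def main():
    cohort = generate_cohort(
        CohortSpec(n=380, hazard_ratio=1 / 3, censoring_rate=0.4, seed=11)
    )
    res = find_optimal_cutpoint(
        cohort.data["eTILs_pct"].to_numpy(), cohort.times, cohort.events,
        min_group_fraction=0.1,
    )
    print(f"recovered cut-point: {res.threshold:.2f}% (true change-point 13.2%)")
    print(f"log-rank chi-square {res.chi_square:.1f}, "
          f"corrected p {res.p_corrected:.2e} "
          f"(raw {res.p_raw:.2e}; correction pays for scanning "
          f"{len(res.scan)} candidate thresholds)")

    high = cohort.data["eTILs_pct"] >= res.threshold
    km_high = kaplan_meier(cohort.times[high], cohort.events[high.to_numpy()])
    km_low = kaplan_meier(cohort.times[~high], cohort.events[~high.to_numpy()])
    print(f"24-month survival: high-TILs {km_high.survival_at(24.0):.2f}, "
          f"low-TILs {km_low.survival_at(24.0):.2f}")

    models = run_table2_models(cohort, etils_threshold=res.threshold)
    uni = models["univariate"]["eTILs"].summary.iloc[0]
    multi = models["multivariate"].summary.loc["eTILs_high"]
    print(f"univariate eTILs HR {uni['hr']:.3f} "
          f"(95% CI {uni['ci_lower']:.3f}-{uni['ci_upper']:.3f})")
    print(f"multivariate eTILs HR {multi['hr']:.3f} "
          f"(adjusted for age, pT, pN, stage, LVI)")
    print("HR < 1: high TILs associate with longer overall survival.")


if __name__ == "__main__":
    main()
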
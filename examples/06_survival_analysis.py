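"""Signature-score survival analysis: cutoff scan, Kaplan-Meier and Cox.

A cohort is simulated under proportional hazards with a true hazard ratio of
0.25 for signature-high patients.  The scan tests every admissible score
cutoff with a log-rank test, Bonferroni-corrects the best raw p by the number
of cutoffs tried, and Cox models (Breslow ties, Wald intervals) quantify the
association alongside clinical covariates.
"""

from oiswaves import survival as surv
from oiswaves.synthetic import SurvivalCohortSpec, generate_cohort

cohort = generate_cohort(SurvivalCohortSpec(seed=1))
print(f"cohort: n = {len(cohort)}, events = {int(cohort['event'].sum())}")

scan = surv.scan_cutoff(cohort["score"], cohort["time"], cohort["event"])
print(f"\ncutoff scan: {scan.n_tested} candidates; best cutoff "
      f"{scan.best_cutoff:.2f}; raw p {scan.p_min:.2e}; "
      f"Bonferroni-adjusted p {scan.adjusted_p:.2e}")

high = (cohort["score"] > scan.best_cutoff).astype(int)
km = surv.km_estimate(cohort["time"], cohort["event"], high)
for g, label in ((0, "low score"), (1, "high score")):
    print(f"  {label}: survival at last event time "
          f"{km[g]['survival'].iloc[-1]:.2f}")

cohort = cohort.assign(high_score=high)
for mode in ("univariate", "multivariate"):
    res = surv.cox_fit(cohort, ["high_score", "site", "resection",
                                "alteration"], mode=mode)
    row = res.table.set_index("predictor").loc["high_score"]
    print(f"\n{mode} Cox, signature-high: HR {row['HR']:.2f} "
          f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}, "
          f"p {row['p']:.2g})")
# An HR well below 1 with an interval excluding 1 reproduces the planted
# protective effect (true HR 0.25) of signature-high status.
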
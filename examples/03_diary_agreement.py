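"""Categorical agreement between nursing diary scores and weighed intake.

Discretizes weighed consumed fractions on the three-level diary scale
([0,0.2]=none, (0.2,0.7]=half, (0.7,1]=all), cross-tabulates them against
the recorded diary scores, and reports percent agreement and Cohen's kappa
(unweighted and quadratic-weighted) with SE-based 95% CIs, plus the
0/50/100% sensitivity analysis.
"""

import numpy as np

from trayintake import GeneratorConfig, generate_cohort, sensitivity_continuous

cohort = generate_cohort(GeneratorConfig(seed=3))
report = sensitivity_continuous(
    cohort.diary_scores, cohort.ai_estimates_g, cohort.true_intake_g, cohort.served_g
)

primary = report["primary"]
print(f"n trays: {primary['n']} (excluded for zero served: {primary['n_excluded_zero_served']})")
print("concordance matrix (rows diary none/half/all, cols measured):")
print(np.asarray(primary["concordance_matrix"]))
print(f"percent agreement: {primary['percent_agreement']:.1f}%")
for w in ("unweighted", "quadratic"):
    k = primary["kappa"][w]
    print(f"kappa ({w}): {k['kappa']:.2f} (95% CI {k['ci'][0]:.2f} to {k['ci'][1]:.2f})")

sens = report["sensitivity"]["kappa"]["quadratic"]
print(f"\nsensitivity (diary as continuous 0/50/100%): kappa_w {sens['kappa']:.2f}")
print(
    "\nDiaries agree with weighing on the diagonal; most disagreements are "
    "adjacent-category, with over-reporting at the 'all' level — quadratic "
    "weights therefore sit above the unweighted kappa."
)
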
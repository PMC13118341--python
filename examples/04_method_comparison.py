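"""Continuous agreement of nursing and AI gram estimates vs weighing.

Reproduces the agreement-table layout — bias, SD of signed errors, RMSE,
Bland–Altman limits of agreement, P10/P15/P30 — for both estimate streams
over trays with non-zero weighed intake, with 5000-iteration percentile
bootstrap CIs for selected statistics.
"""

import json

from trayintake import BootstrapConfig, GeneratorConfig, compare_methods, generate_cohort

cohort = generate_cohort(GeneratorConfig(n_patients=200, trays_per_patient_mean=5.0, seed=8))
report = compare_methods(
    cohort.nursing_pairs(),
    cohort.ai_pairs(),
    config=BootstrapConfig(n_boot=5000, seed=8),
    ci_statistics=("bias", "rmse"),
)

print(json.dumps(report.to_dict(), indent=1))
print(
    "\nThe AI stream shows a systematic negative bias (underestimation) with "
    "small dispersion; the diary stream is nearly unbiased on average but far "
    "more variable tray to tray (wider limits of agreement, lower P10/P15/P30)."
)
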
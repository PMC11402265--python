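"""Case-control discrimination: shape scores vs conventional measures.

Runs the full 63 + 63 cohort through the landmark and measurement stages,
then fits the three logistic regression models (shape-mode scores only,
conventional measurements only, both combined) and prints their in-sample
AUC, sensitivity and specificity at the 0.5 probability cut-off, plus the
per-mode Mann-Whitney screen.  AUC 0.5 is chance; higher is better
separation of the late-endoleak cases from controls.
"""

import numpy as np

import neckssm as ns
from neckssm.pipeline import cohort_to_necks_and_measures
from neckssm.ssm import build_ssm, project_cohort
from neckssm.stats import run_models

subjects = ns.sample_cohort(seed=11, geometry="centerline")
necks, measures = cohort_to_necks_and_measures(subjects, analytic=True, seed=12)
aligned = ns.align_necks(necks)
model = build_ssm(aligned)
scores = project_cohort(aligned, model)

out = run_models(scores, measures)
print("model          AUC    sens   spec")
for r in out["results"].values():
    print(f"{r.label:13s} {r.auc:.3f}  {r.sensitivity * 100:4.0f}%  {r.specificity * 100:4.0f}%")
print(f"modes with significant group difference (p < 0.05): {out['significant_pcs']}")
print()
print("variable            case median  control median  p")
for t in out["measure_tests"]:
    print(f"{t.variable:20s} {t.median_a:10.1f}  {t.median_b:12.1f}  {t.p_value:.3f}")
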
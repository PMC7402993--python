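#!/usr/bin/env python
"""Check adequacy of the fitted reference models.

For every persisted model: centile coverage (fraction of eligible subjects
below each curve vs nominal) and Kolmogorov-Smirnov normality of z-scores,
Holm-corrected across the model family.  Writes results/validation.csv.
"""

from pathlib import Path

import pandas as pd

from lmsref import apply_exclusions, compute_indices, validate_reference_set
from lmsref.io import model_from_yaml, read_cohort_csv
from lmsref.lms_core import FitData

RESULTS = Path(__file__).resolve().parent.parent / "results"

cohort = compute_indices(read_cohort_csv(RESULTS / "cohort.csv"))
body, _ = apply_exclusions(cohort, "body_composition")
vat, _ = apply_exclusions(cohort, "vat")

models, data = {}, {}
for path in sorted((RESULTS / "reference" / "models").glob("*.yaml")):
    m = model_from_yaml(path)
    pool = vat if m.parameter_name == "vat_mass" else body
    sub = pool[pool.sex == m.sex]
    models[(m.parameter_name, m.sex)] = m
    data[(m.parameter_name, m.sex)] = FitData(
        sub.age.to_numpy(), sub[m.parameter_name].to_numpy()
    )

reports = validate_reference_set(models, data)
rows = []
for rep in reports:
    cov = {f"below_P{r.percentile:g}_pct": 100 * r.fraction_below
           for r in rep.coverage.itertuples()}
    rows.append(
        {
            "parameter": rep.parameter_name,
            "sex": rep.sex,
            "ks_p_adjusted": round(rep.ks_p_adjusted, 4),
            "passed": rep.passed,
            **{k: round(v, 2) for k, v in cov.items()},
        }
    )
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "validation.csv", index=False)
print(table.to_string(index=False))
print(f"\n{int(table.passed.sum())}/{len(table)} models pass "
      "(Holm-adjusted KS p >= 0.05 and coverage within 2 percentage points)")
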
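"""Cohort-level statistics and the final machine-readable report.

Tumor-fraction estimates (2x median VAF, samples with > 10 calls),
burden-grade Spearman correlation on OxoG-passing samples, exact-test
association of the planted recurrent regions with grade, and the
TP53-mutation / 17p-like-deletion co-occurrence breakdown.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, cohort_calls, default_cohort
from pjflow.calling import burden
from pjflow.oxog import flag_oxog_samples, sample_evidence
from pjflow.stats import (SampleRecord, cohort_report, cooccurrence,
                          estimate_tumor_fraction,
                          region_grade_association, spearman_burden_grade,
                          write_report)

cohort = default_cohort()
calls = cohort_calls(cohort)

oxog_qc = flag_oxog_samples(
    [sample_evidence(sid, calls[sid]) for sid in calls]
).set_index("sample_id")
cna_qc = pd.read_csv(RESULTS / "04_residual_variance_qc.tsv",
                     sep="\t").set_index("sample_id")

records = []
for s in cohort.samples:
    sid = s.sample_id
    s.n_pass = burden(calls[sid])
    s.tumor_fraction = estimate_tumor_fraction(calls[sid])
    s.oxog_excluded = bool(oxog_qc.loc[sid, "excluded"])
    s.cna_excluded = bool(cna_qc.loc[sid, "excluded"])
    truth_segs = cohort.truth.segments[sid]
    s.region_flags = {
        p.name: bool((truth_segs["name"] == p.name).any())
        for p in cohort.config.cna_profiles}
    s.tp53_mutation = any(e.gene == "TP53"
                          for e in cohort.truth.events[sid])
    records.append(s)

snv_ok = [s for s in records if not s.oxog_excluded]
rho, p = spearman_burden_grade([s.grade for s in snv_ok],
                               [s.n_pass for s in snv_ok])
fractions = [s.tumor_fraction for s in snv_ok
             if s.tumor_fraction is not None]

cna_ok = [s for s in records if not s.cna_excluded]
assoc = region_grade_association(
    {name: [s.region_flags[name] for s in cna_ok]
     for name in records[0].region_flags},
    [s.grade for s in cna_ok])
assoc.to_csv(RESULTS / "06_region_grade_association.tsv", sep="\t",
             index=False, float_format="%.6g")

cooc = cooccurrence([s.tp53_mutation for s in records],
                    [s.region_flags["del_17p13_like"] for s in records],
                    [s.grade for s in records])

class_counts: dict = {}
for s in snv_ok:
    for c in calls[s.sample_id]:
        if c.passed:
            class_counts[c.consequence] = \
                class_counts.get(c.consequence, 0) + 1

report = cohort_report(records, class_counts=class_counts,
                       region_association=assoc,
                       cooccurrence_result=cooc)
write_report(RESULTS / "06_cohort_report.json", report)

print(f"burden-grade Spearman rho = {rho:.3f} (p = {p:.3g}, "
      f"n = {len(snv_ok)})")
print(f"median tumor fraction = {100 * np.median(fractions):.1f}% "
      f"(n = {len(fractions)} samples with > 10 calls)")
print("region-grade association (QC-passing CNA cohort, "
      f"n = {len(cna_ok)}):")
print(assoc.to_string(index=False))
both = cooc["by_grade"].get("INC", {}).get("both", 0)
print(f"TP53-mutant samples with the 17p-like deletion, INC: {both}; "
      f"LGD/HGD: "
      f"{sum(cooc['by_grade'].get(g, {}).get('both', 0) for g in ('LGD', 'HGD'))}")
print(f"report: {RESULTS / '06_cohort_report.json'}")
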
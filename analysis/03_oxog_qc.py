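"""Three-evidence OxoG sample QC on the called cohort.

Per sample: median VAF of PASS calls, the CCN-context C>A oxidation
score, and the spectrum signature score; cohort-relative outlier flags
(median +/- 3 MAD) combine 2-of-3 into the exclusion decision. The
excluded set is compared against the injected truth.
"""

from _common import RESULTS, cohort_calls, default_cohort
from pjflow.oxog import flag_oxog_samples, sample_evidence

cohort = default_cohort()
calls = cohort_calls(cohort)

evidences = [sample_evidence(sid, calls[sid]) for sid in calls]
table = flag_oxog_samples(evidences)
table.to_csv(RESULTS / "03_oxog_qc.tsv", sep="\t", index=False,
             float_format="%.6g")

excluded = set(table.loc[table["excluded"], "sample_id"])
injected = {sid for sid, ox in cohort.truth.oxog.items() if ox}
print(f"excluded {sorted(excluded)} (injected truth: {sorted(injected)})")
print("exact match" if excluded == injected else "MISMATCH")
clean = table[~table["excluded"]]
dirty = table[table["excluded"]]
print(f"median oxidation score: clean {clean['oxidation_score'].median():.3f}"
      f" vs excluded {dirty['oxidation_score'].median():.3f}")
print(f"median VAF: clean {clean['median_vaf'].median():.3f}"
      f" vs excluded {dirty['median_vaf'].median():.3f}")
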
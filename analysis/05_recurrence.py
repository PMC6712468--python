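"""Recurrent amplification/deletion detection across the QC-passing
cohort, whole-cohort and per grade subset (benign vs malignant).

Segments from 04 are projected onto bin-midpoint markers; G-scores with
a cyclic-shift permutation null give q-values and 0.90-confidence driver
intervals. Detected regions are compared with the planted recurrent
events (amp on chromosome 2, amp on chromosome 3, del on chromosome 5).
"""

import numpy as np
import pandas as pd

from _common import COHORT_SEED, RESULTS, default_cohort
from pjflow.cna import read_seg
from pjflow.recurrence import (find_recurrent_regions,
                               marker_matrix_from_seg, per_grade_runs,
                               regions_to_frame)

cohort = default_cohort()
segments = read_seg(RESULTS / "04_segments.seg")
qc = pd.read_csv(RESULTS / "04_residual_variance_qc.tsv", sep="\t")
keep = set(qc.loc[~qc["excluded"], "sample_id"])
segments = segments[segments["sample_id"].isin(keep)]

mm = marker_matrix_from_seg(segments,
                            cohort.bins[cohort.bins["on_target"]])
grades = [cohort.truth.grade[sid] for sid in mm.sample_ids]

rng = np.random.default_rng(COHORT_SEED + 2)
frames = []
for direction in ("amp", "del"):
    regions = find_recurrent_regions(mm, direction, seed=rng,
                                     grades=grades)
    f = regions_to_frame(regions)
    f["subset"] = "all"
    frames.append(f)
    for name, regs in per_grade_runs(mm, grades, direction,
                                     seed=COHORT_SEED + 3).items():
        f = regions_to_frame(regs)
        f["subset"] = name
        frames.append(f)

out = pd.concat(frames, ignore_index=True)
out.to_csv(RESULTS / "05_recurrent_regions.tsv", sep="\t", index=False,
           float_format="%.6g")

truth = {(p.chrom, "amp" if p.log2 > 0 else "del"): (p.start, p.end)
         for p in cohort.config.cna_profiles}
whole = out[out["subset"] == "all"]
print(f"{len(whole)} regions in the whole-cohort run "
      f"({(whole['direction'] == 'amp').sum()} amp / "
      f"{(whole['direction'] == 'del').sum()} del)")
for (chrom, direction), (start, end) in sorted(truth.items()):
    hit = whole[(whole["chrom"] == chrom) &
                (whole["direction"] == direction) &
                (whole["peak_start"] >= start - 5000) &
                (whole["peak_start"] < end + 5000)]
    status = "recovered" if len(hit) else "missed"
    q = f" (q={hit['q_value'].min():.3g})" if len(hit) else ""
    print(f"  planted {direction} {chrom}:{start}-{end}: {status}{q}")
print(out.groupby("subset").size().to_string())
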
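"""Shared setup for the analysis scripts: one default cohort, one seed.

Every script regenerates the cohort deterministically from COHORT_SEED,
so the scripts can be run independently and in any order; heavyweight
per-read fixtures go under scratch/, small result tables under results/.
"""

from pathlib import Path

from pjflow.calling import annotate_calls, call_sample
from pjflow.synthetic import CohortConfig, simulate_cohort, truth_annotation

COHORT_SEED = 2019
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def default_cohort():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return simulate_cohort(CohortConfig(seed=COHORT_SEED))


def cohort_calls(cohort):
    """Call every sample and carry over the truth consequence labels
    (standing in for the external annotation step)."""
    out = {}
    for sid, pu in cohort.pileups.items():
        calls = call_sample(pu)
        annotate_calls(calls, truth_annotation(cohort.truth.events[sid]))
        out[sid] = calls
    return out
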
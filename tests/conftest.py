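"""Shared fixtures: a scaled-down synthetic cohort reused across modules."""

import dataclasses

import pytest

from pjflow.synthetic import CnaProfileSpec, CohortConfig, simulate_cohort


def small_config(**overrides) -> CohortConfig:
    """Desk-scale cohort: 2 chromosomes, 9 samples, shallow null set."""
    base = dict(
        n_samples_per_grade=(3, 3, 3),
        chrom_sizes={"1": 120_000, "2": 120_000},
        cna_profiles=(
            CnaProfileSpec("amp_7q21_like", "1", 30_000, 60_000, 0.6,
                           (0.14, 0.06, 0.64)),
            CnaProfileSpec("del_17p13_like", "2", 40_000, 70_000, -0.6,
                           (0.10, 0.20, 0.45)),
        ),
        n_null_sites=40,
        n_oxog_samples=0,
        noisy_sample_fraction=0.0,
        seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    from pjflow.calling import call_sample

    return {sid: call_sample(pu)
            for sid, pu in small_cohort.pileups.items()}
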
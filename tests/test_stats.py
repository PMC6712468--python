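"""Cohort statistics: tumor fraction, Spearman, association, reports."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from pjflow.calling import MutationCall
from pjflow.stats import (SampleRecord, cohort_report, cooccurrence,
                          estimate_tumor_fraction, region_grade_association,
                          spearman_burden_grade, _pct)


def pass_call(vaf, pos=100):
    return MutationCall("1", pos, "C", "A", "ACA", 30, 70, 0, 100, vaf,
                        0.0, 1e-6, "PASS")


def test_tumor_fraction_doubles_median_vaf():
    calls = [pass_call(0.25, pos=i) for i in range(11)]
    assert estimate_tumor_fraction(calls) == pytest.approx(0.5)


def test_tumor_fraction_requires_more_than_ten_calls():
    calls = [pass_call(0.25, pos=i) for i in range(10)]
    assert estimate_tumor_fraction(calls) is None


def test_tumor_fraction_clipped_to_unit():
    calls = [pass_call(0.8, pos=i) for i in range(12)]
    assert estimate_tumor_fraction(calls) == 1.0


def test_tumor_fraction_recovers_purity():
    from pjflow.calling import call_sample
    from pjflow.synthetic import simulate_clonal_sample

    pu = simulate_clonal_sample(30, purity=0.4, seed=2, depth_tumor=200)
    est = estimate_tumor_fraction(call_sample(pu))
    assert est == pytest.approx(0.4, abs=0.05)


def test_spearman_perfect_orders():
    rho, p = spearman_burden_grade([1, 2, 3], [10, 20, 30])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman_burden_grade([1, 2, 3], [30, 20, 10])
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_grade_undefined():
    rho, p = spearman_burden_grade([2, 2, 2, 2], [1, 2, 3, 4])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_matches_midrank_oracle_with_ties():
    grades = [1, 1, 2, 2, 2, 3, 3, 3, 3, 1, 2, 3]
    burdens = [5, 9, 9, 14, 3, 22, 22, 40, 18, 7, 11, 30]
    rho, _ = spearman_burden_grade(grades, burdens)
    rx, ry = rankdata(grades), rankdata(burdens)
    oracle = float(np.corrcoef(rx, ry)[0, 1])
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_exact_permutation_p_small_n():
    """n < 10 uses full enumeration; check against a direct oracle."""
    grades = [1, 1, 2, 2, 3, 3]
    burdens = [4, 6, 5, 9, 12, 11]
    rho, p = spearman_burden_grade(grades, burdens)
    rx, ry = rankdata(grades), rankdata(burdens)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    hits = total = 0
    for perm in itertools.permutations(range(6)):
        r = float(np.dot(rxc, ryc[list(perm)]) / denom)
        hits += abs(r) >= abs(rho) - 1e-12
        total += 1
    assert p == pytest.approx(hits / total, abs=1e-12)


def test_spearman_invariant_under_monotone_transform():
    grades = [1, 2, 3, 1, 2, 3, 2, 3, 1, 2, 3, 3]
    burdens = [3, 8, 20, 5, 12, 25, 7, 31, 2, 15, 27, 18]
    rho1, _ = spearman_burden_grade(grades, burdens)
    rho2, _ = spearman_burden_grade(grades,
                                    [math.exp(b / 5) for b in burdens])
    assert rho1 == pytest.approx(rho2, abs=1e-12)


def test_region_association_fractions_and_p():
    grades = [1] * 7 + [2] * 17 + [3] * 11
    flags = [True] + [False] * 6 + [True] + [False] * 16 + \
        [True] * 7 + [False] * 4
    df = region_grade_association({"amp_7q21": flags}, grades)
    row = df.iloc[0]
    assert row["pct_LGD"] == 14.29
    assert row["pct_HGD"] == 5.88
    assert row["pct_INC"] == 63.64
    assert row["p_value"] == pytest.approx(0.002, abs=0.0005)


def test_region_absent_everywhere_gives_p_one():
    df = region_grade_association({"empty": [False] * 10},
                                  [1] * 3 + [2] * 4 + [3] * 3)
    assert df["p_value"].iloc[0] == 1.0
    assert df["pct_LGD"].iloc[0] == 0.0


def test_region_sorting_by_p():
    grades = [1] * 5 + [3] * 5
    strong = [False] * 5 + [True] * 5
    weak = [False] * 9 + [True]
    df = region_grade_association({"weak": weak, "strong": strong}, grades)
    assert df["region"].tolist() == ["strong", "weak"]


def test_cooccurrence_counts():
    a = [True, True, False, False, True]
    b = [True, False, True, False, True]
    grades = [3, 3, 2, 1, 3]
    out = cooccurrence(a, b, grades)
    assert out["overall"] == {"both": 2, "a_only": 1, "b_only": 1,
                              "neither": 1}
    assert out["by_grade"]["INC"]["both"] == 2
    assert out["by_grade"]["LGD"]["neither"] == 1


def test_cooccurrence_trivial_cases():
    out = cooccurrence([False] * 4, [False] * 4)
    assert out["overall"] == {"both": 0, "a_only": 0, "b_only": 0,
                              "neither": 4}
    same = [True, False, True]
    out = cooccurrence(same, same)
    assert out["overall"]["a_only"] == 0 and out["overall"]["b_only"] == 0


def test_percent_rounding_half_up():
    assert _pct(14 / 32) == 43.75
    assert _pct(5 / 32) == 15.63
    assert _pct(1 / 7) == 14.29
    assert _pct(0.125) == 12.5


def records():
    rng = np.random.default_rng(3)
    recs = []
    for i in range(12):
        grade = 1 + i % 3
        recs.append(SampleRecord(
            f"s{i}", grade, n_pass=int(5 + 10 * grade + rng.integers(0, 5)),
            tumor_fraction=float(rng.uniform(0.1, 0.6))))
    return recs


def test_cohort_report_consistent_with_direct_calls():
    recs = records()
    report = cohort_report(recs, class_counts={"missense": 9, "splice": 1})
    rho, p = spearman_burden_grade([r.grade for r in recs],
                                   [r.n_pass for r in recs])
    assert report["burden_grade_spearman"]["rho"] == pytest.approx(
        rho, rel=1e-5)
    assert report["median_tumor_fraction"] == pytest.approx(
        float(np.median([r.tumor_fraction for r in recs])), rel=1e-5)
    assert report["consequence_classes"]["missense"]["percent"] == 90.0
    assert report["n_samples"] == 12


def test_cohort_report_deterministic_and_empty_ok():
    import json

    assert json.dumps(cohort_report(records())) == \
        json.dumps(cohort_report(records()))
    empty = cohort_report([])
    assert empty["n_samples"] == 0 and empty["samples"] == []


def test_excluded_samples_leave_snv_statistics():
    recs = records()
    for r in recs[:3]:
        r.oxog_excluded = True
    report = cohort_report(recs)
    assert report["n_snv_analyzed"] == 9
    rho, _ = spearman_burden_grade([r.grade for r in recs[3:]],
                                   [r.n_pass for r in recs[3:]])
    assert report["burden_grade_spearman"]["rho"] == pytest.approx(
        rho, rel=1e-5)
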
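"""Somatic caller: read filtering, filter chain, class tallies."""

import numpy as np
import pytest

from pjflow.calling import (CallerConfig, burden, call_sample, call_site,
                            classify_and_count, filter_reads)
from pjflow.pileup import SamplePileup, make_site


def site_with(tumor, normal, ref="C", context="ACA", pos=100):
    return make_site("1", pos, ref, context, tumor, normal)


def reads(allele, n, baseq=35.0, mapq=60.0):
    return [(allele, baseq, mapq)] * n


def test_low_mapq_reads_all_dropped():
    site = site_with(reads("C", 30, mapq=19.0), reads("C", 30, mapq=19.0))
    t, n = filter_reads(site, CallerConfig())
    assert sum(t.values()) == 0 and sum(n.values()) == 0


def test_empty_site_gives_zero_counts():
    site = site_with([], [])
    t, n = filter_reads(site, CallerConfig())
    assert sum(t.values()) == 0 and sum(n.values()) == 0


def test_filter_reads_matches_per_read_recount():
    """Retained counts equal a brute-force scan over every read."""
    rng = np.random.default_rng(5)
    cfg = CallerConfig()
    for _ in range(20):
        def rand_reads(k):
            return [(rng.choice(list("ACGT")), float(rng.uniform(0, 41)),
                     float(rng.uniform(0, 60))) for _ in range(k)]
        tumor, normal = rand_reads(40), rand_reads(25)
        site = site_with(tumor, normal)
        t, n = filter_reads(site, cfg)
        for obs, counts in ((tumor, t), (normal, n)):
            brute = {}
            for a, bq, mq in obs:
                if mq >= cfg.min_mapq and bq >= cfg.min_baseq:
                    brute[a] = brute.get(a, 0) + 1
            assert dict(counts) == brute


@pytest.mark.parametrize("tumor,normal,expected_filter", [
    # filtered tumor depth 7 < 8
    (reads("A", 3) + reads("C", 4), reads("C", 50), "depth_fail"),
    # 2 alt reads of 100
    (reads("A", 2) + reads("C", 98), reads("C", 100),
     "min_variant_reads_fail"),
    # VAF 4/100 < 0.05
    (reads("A", 4) + reads("C", 96), reads("C", 100), "tumor_af_fail"),
    # normal VAF 15/100 > 0.1
    (reads("A", 30) + reads("C", 70), reads("A", 15) + reads("C", 85),
     "normal_af_fail"),
    # balanced table: normal VAF exactly 0.1 passes, Fisher p ~ 1 fails
    (reads("A", 10) + reads("C", 90), reads("A", 10) + reads("C", 90),
     "fisher_fail"),
    # clean somatic signal
    (reads("A", 30) + reads("C", 70), reads("C", 100), "PASS"),
])
def test_filter_chain_names_first_failure(tumor, normal, expected_filter):
    call = call_site(site_with(tumor, normal), CallerConfig())
    assert call is not None
    assert call.filter == expected_filter


def test_pass_implies_all_thresholds(small_cohort_calls):
    cfg = CallerConfig()
    checked = 0
    for calls in small_cohort_calls.values():
        for c in calls:
            if not c.passed:
                continue
            checked += 1
            assert c.tumor_alt >= cfg.min_variant_reads
            assert c.tumor_alt + c.tumor_ref >= cfg.min_depth
            assert c.tumor_vaf >= cfg.min_tumor_af
            assert c.normal_vaf <= cfg.max_normal_af
            assert c.p_value <= cfg.fisher_threshold
    assert checked > 50


def test_unsorted_pileup_rejected():
    sites = [site_with(reads("C", 20), reads("C", 20), pos=200),
             site_with(reads("C", 20), reads("C", 20), pos=100)]
    with pytest.raises(ValueError):
        call_sample(SamplePileup("s", sites))


def test_calling_is_deterministic(small_cohort):
    pu = next(iter(small_cohort.pileups.values()))
    a = call_sample(pu)
    b = call_sample(pu)
    assert [(c.chrom, c.pos, c.alt, c.p_value, c.filter) for c in a] == \
        [(c.chrom, c.pos, c.alt, c.p_value, c.filter) for c in b]


def test_truth_recovery_on_synthetic_sample(small_cohort, small_cohort_calls):
    """High-VAF truth events are recovered; false PASS calls are rare."""
    hits = total = false = null_sites = 0
    for sid, calls in small_cohort_calls.items():
        truth = {(e.chrom, e.pos) for e in small_cohort.truth.events[sid]}
        purity = small_cohort.truth.purity[sid]
        strong = {(e.chrom, e.pos)
                  for e in small_cohort.truth.events[sid]
                  if purity * e.ccf / 2.0 >= 0.1}
        passed = {(c.chrom, c.pos) for c in calls if c.passed}
        hits += len(strong & passed)
        total += len(strong)
        false += len(passed - truth)
        null_sites += small_cohort.config.n_null_sites
    assert total > 20
    assert hits / total >= 0.95
    assert false / null_sites < 0.01


def test_class_percentages_round_half_up():
    counts = {"missense": 494, "frameshift_del": 30, "nonsense": 25,
              "frameshift_ins": 15, "splice": 10, "inframe_del": 5}
    df = classify_and_count(counts).set_index("consequence")
    assert df.loc["missense", "percent"] == 85.32
    assert df.loc["frameshift_del", "percent"] == 5.18
    assert df.loc["nonsense", "percent"] == 4.32
    assert df["count"].sum() == 579


def test_single_call_is_hundred_percent():
    df = classify_and_count({"splice": 1})
    assert df["percent"].tolist() == [100.0]


def test_burden_counts_pass_only(small_cohort_calls):
    for calls in small_cohort_calls.values():
        assert burden(calls) == sum(c.passed for c in calls)
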
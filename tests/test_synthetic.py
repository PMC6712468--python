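"""Synthetic cohort generator: calibration, determinism, fixtures."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from conftest import small_config
from pjflow.oxog import pyrimidine_strand
from pjflow.synthetic import (CohortConfig, nb_mean_for_median, read_fixture,
                              simulate_clonal_sample, simulate_cohort,
                              write_fixture)


def test_zero_burden_gives_empty_truth():
    cohort = simulate_cohort(small_config(
        burden_median_by_grade=(0.0, 0.0, 0.0), n_null_sites=5))
    assert all(len(ev) == 0 for ev in cohort.truth.events.values())


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(depth_tumor=0)
    with pytest.raises(ValueError):
        CohortConfig(chrom_sizes={})
    with pytest.raises(ValueError):
        CohortConfig(noisy_sample_fraction=1.5)


def test_burden_medians_calibrated():
    """Grade medians land within 20% of the configured targets."""
    cfg = small_config(n_samples_per_grade=(60, 60, 60), n_null_sites=0,
                       seed=7)
    cohort = simulate_cohort(cfg)
    by_grade = {1: [], 2: [], 3: []}
    for sid, events in cohort.truth.events.items():
        by_grade[cohort.truth.grade[sid]].append(
            sum(not e.artifact for e in events))
    for g, target in zip((1, 2, 3), cfg.burden_median_by_grade):
        med = float(np.median(by_grade[g]))
        assert med == pytest.approx(target, rel=0.2)
    meds = [np.median(by_grade[g]) for g in (1, 2, 3)]
    assert meds == sorted(meds)


def test_nb_median_calibration_direct():
    from scipy.stats import nbinom

    for target in (16.0, 19.5, 64.0):
        mu = nb_mean_for_median(target, dispersion=8.0)
        p = 8.0 / (8.0 + mu)
        assert nbinom.ppf(0.5, 8.0, p) == pytest.approx(
            np.floor(target), abs=1.0)


def test_vaf_calibration_at_truth_sites():
    """Mean tumor VAF over clonal events approaches purity / 2."""
    pu = simulate_clonal_sample(n_events=400, purity=0.4, seed=13,
                                depth_tumor=200)
    vafs = []
    for site in pu.sites:
        alt = [a for a in site.tumor_alleles if a != site.ref]
        vafs.append(len(alt) / site.tumor_depth)
    assert float(np.mean(vafs)) == pytest.approx(0.20, abs=0.01)


def test_oxog_injection_rate_zero_is_identity():
    from pjflow.reference import SyntheticReference
    from pjflow.synthetic import inject_oxog
    from pjflow.pileup import SamplePileup

    ref = SyntheticReference.generate({"1": 1000}, seed=0)
    pu = SamplePileup("s", [])
    out = inject_oxog(pu, ref, [("1", 5)], 0, np.random.default_rng(0),
                      small_config())
    assert out is pu and len(pu) == 0


def test_injected_sites_are_ccn_context_c_to_a():
    cfg = small_config(n_oxog_samples=9, oxog_sites_per_sample=200, seed=3)
    cohort = simulate_cohort(cfg)
    checked = 0
    ok = 0
    for sid, events in cohort.truth.events.items():
        for e in events:
            if not e.artifact:
                continue
            checked += 1
            ctx = cohort.reference.context(e.chrom, e.pos)
            sub, pyr_ctx = pyrimidine_strand(e.ref, e.alt, ctx)
            ok += sub == "C>A" and pyr_ctx[0] == "C"
    assert checked >= 200
    assert ok / checked >= 0.95


def test_truth_events_lie_within_targets(small_cohort):
    from pjflow.intervals import overlaps_any

    for events in small_cohort.truth.events.values():
        for e in events:
            assert overlaps_any(small_cohort.targets, e.chrom,
                                e.pos - 1, e.pos)
            assert e.artifact or 0 < e.ccf <= 1


def _dir_hashes(d: Path) -> dict:
    out = {}
    for f in sorted(d.rglob("*")):
        if f.is_file():
            out[str(f.relative_to(d))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    return out


def test_same_seed_fixture_is_byte_identical(tmp_path):
    cfg = small_config(n_samples_per_grade=(1, 1, 1), n_null_sites=10)
    a, b = tmp_path / "a", tmp_path / "b"
    write_fixture(a, simulate_cohort(cfg))
    write_fixture(b, simulate_cohort(cfg))
    ha, hb = _dir_hashes(a), _dir_hashes(b)
    assert ha == hb and len(ha) > 5


def test_different_seed_changes_fixture(tmp_path):
    cfg = small_config(n_samples_per_grade=(1, 1, 1), n_null_sites=10)
    cfg2 = dataclasses.replace(cfg, seed=cfg.seed + 1)
    a, b = tmp_path / "a", tmp_path / "b"
    write_fixture(a, simulate_cohort(cfg))
    write_fixture(b, simulate_cohort(cfg2))
    assert _dir_hashes(a) != _dir_hashes(b)


def test_fixture_roundtrip_preserves_cohort(tmp_path):
    cfg = small_config(n_samples_per_grade=(1, 1, 1), n_null_sites=10,
                       n_oxog_samples=1, oxog_sites_per_sample=20)
    cohort = simulate_cohort(cfg)
    write_fixture(tmp_path / "fx", cohort)
    back = read_fixture(tmp_path / "fx")
    assert back.config == cohort.config
    assert [s.sample_id for s in back.samples] == \
        [s.sample_id for s in cohort.samples]
    for sid in cohort.pileups:
        orig, rt = cohort.pileups[sid], back.pileups[sid]
        assert len(orig) == len(rt)
        for s1, s2 in zip(orig.sites, rt.sites):
            assert (s1.chrom, s1.pos, s1.ref, s1.context) == \
                (s2.chrom, s2.pos, s2.ref, s2.context)
            assert list(s1.tumor_alleles) == list(s2.tumor_alleles)
            assert np.allclose(s1.tumor_baseq, s2.tumor_baseq, rtol=1e-4)
        ev1, ev2 = cohort.truth.events[sid], back.truth.events[sid]
        assert [(e.chrom, e.pos, e.ref, e.alt, e.artifact) for e in ev1] == \
            [(e.chrom, e.pos, e.ref, e.alt, e.artifact) for e in ev2]
        for e1, e2 in zip(ev1, ev2):
            assert e1.ccf == pytest.approx(e2.ccf, rel=1e-5, nan_ok=True)
        t1, n1 = cohort.bin_counts[sid]
        t2, n2 = back.bin_counts[sid]
        assert np.array_equal(t1, t2) and np.array_equal(n1, n2)
        assert back.truth.purity[sid] == pytest.approx(
            cohort.truth.purity[sid], rel=1e-5)
    assert back.truth.grade == cohort.truth.grade
    assert back.truth.oxog == cohort.truth.oxog


def test_empty_cohort_fixture(tmp_path):
    cfg = small_config(n_samples_per_grade=(0, 0, 0))
    cohort = simulate_cohort(cfg)
    write_fixture(tmp_path / "fx", cohort)
    back = read_fixture(tmp_path / "fx")
    assert back.samples == [] and back.pileups == {}


def test_noisy_samples_have_inflated_bin_noise():
    cfg = small_config(n_samples_per_grade=(6, 6, 6),
                       noisy_sample_fraction=0.2, passenger_rate=0.0,
                       cna_profiles=(), n_null_sites=0,
                       burden_median_by_grade=(0, 0, 0), seed=9)
    cohort = simulate_cohort(cfg)
    spreads = {}
    for sid, (t, n) in cohort.bin_counts.items():
        log2 = np.log2(np.maximum(t, 1) / np.maximum(n, 1))
        spreads[sid] = np.std(log2)
    noisy = [s for s, flag in cohort.truth.noisy.items() if flag]
    clean = [s for s, flag in cohort.truth.noisy.items() if not flag]
    assert len(noisy) == round(0.2 * 18)
    assert min(spreads[s] for s in noisy) > \
        2.5 * max(spreads[s] for s in clean)
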
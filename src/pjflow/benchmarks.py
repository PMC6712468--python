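"""Pipeline validation experiments on synthetic data.

Each function runs one end-to-end calibration or recovery experiment at
desk scale — type-I error of the site test, tumor-fraction recovery,
CBS breakpoint recovery, recurrence detection power, and the two sample-QC
screens — and returns the measured rate. The experiment sizes are chosen
so each completes in seconds to a couple of minutes on one core; the same
functions back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import cbs
from .calling import CallerConfig, call_sample
from .oxog import flag_oxog_samples, sample_evidence
from .recurrence import MarkerMatrix, find_recurrent_regions
from .stats import estimate_tumor_fraction
from .synthetic import (CohortConfig, simulate_clonal_sample,
                        simulate_cohort, simulate_marker_cohort,
                        simulate_null_sites)


def caller_type1_error(n_sites: int = 10_000, depth: float = 100.0,
                       af: float = 0.5, seed: int = 0) -> float:
    """Fraction of null sites called significant at the 0.05 threshold.

    Null sites share the same allele fraction in tumor and normal
    (germline-heterozygous-like); among sites passing the depth and
    supporting-read thresholds, a calibrated one-sided Fisher test keeps
    this fraction at or below the nominal level.
    """
    pu = simulate_null_sites(n_sites, depth_tumor=depth, depth_normal=depth,
                             af=af, seed=seed)
    calls = call_sample(pu, CallerConfig())
    eligible = [c for c in calls
                if c.filter not in ("depth_fail", "min_variant_reads_fail")]
    if not eligible:
        return 0.0
    return float(np.mean([c.p_value <= 0.05 for c in eligible]))


def tumor_fraction_mae(n_samples: int = 50, purity_lo: float = 0.1,
                       purity_hi: float = 0.8, n_events: int = 30,
                       depth: float = 200.0, seed: int = 0) -> float:
    """Mean absolute error of the 2x-median-VAF tumor-fraction estimator."""
    ss = np.random.SeedSequence(seed)
    purities = np.linspace(purity_lo, purity_hi, n_samples)
    errors = []
    for purity, child in zip(purities, ss.spawn(n_samples)):
        pu = simulate_clonal_sample(n_events, float(purity),
                                    seed=child, depth_tumor=depth)
        est = estimate_tumor_fraction(call_sample(pu))
        errors.append(abs((est if est is not None else 0.0) - purity))
    return float(np.mean(errors))


def cbs_recovery_rate(n_reps: int = 100, n_bins: int = 100,
                      shift: float = 1.0, noise_sd: float = 0.1,
                      tolerance: int = 2, seed: int = 0) -> float:
    """Fraction of single-breakpoint profiles recovered within tolerance."""
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        b = int(rng.integers(n_bins // 5, 4 * n_bins // 5))
        x = rng.normal(0.0, noise_sd, n_bins)
        x[b:] += shift
        segs = cbs.cbs_segment(x, seed=rng)
        hits += len(segs) == 2 and abs(segs[0][1] - b) <= tolerance
    return hits / n_reps


def recurrence_power(n_cohorts: int = 50, n_samples: int = 35,
                     n_markers: int = 200, prevalence: float = 0.5,
                     amplitude: float = 0.8, spike_len: int = 10,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Detection power for a recurrently amplified span of markers."""
    ss = np.random.SeedSequence(seed)
    start = n_markers // 2
    hits = 0
    for child in ss.spawn(n_cohorts):
        rng = np.random.default_rng(child)
        X, _ = simulate_marker_cohort(
            n_samples, n_markers, seed=rng,
            spike=(start, spike_len, amplitude, prevalence))
        mm = MarkerMatrix(np.array(["1"] * n_markers),
                          np.arange(n_markers) * 1000, X,
                          [f"s{i}" for i in range(n_samples)])
        regs = find_recurrent_regions(mm, "amp", n_perm=n_perm, seed=rng)
        lo, hi = start * 1000, (start + spike_len) * 1000
        hits += any(r.q < 0.25 and lo <= r.peak_start < hi for r in regs)
    return hits / n_cohorts


def _oxog_config(seed: int) -> CohortConfig:
    return CohortConfig(
        n_samples_per_grade=(7, 8, 8),
        chrom_sizes={"1": 150_000, "2": 150_000},
        cna_profiles=(), passenger_rate=0.0,
        n_null_sites=30, noisy_sample_fraction=0.0,
        n_oxog_samples=3, oxog_sites_per_sample=120, seed=seed)


def oxog_flagging_accuracy(n_reps: int = 20, seed: int = 0) -> float:
    """Fraction of cohorts where exactly the injected samples are excluded.

    Each replicate cohort holds 20 clean and 3 OxoG-injected samples; the
    full path (simulate, call, three-evidence QC) must single out the
    injected trio with no false exclusions.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cohort = simulate_cohort(_oxog_config(int(rng.integers(2 ** 31))))
        evidences = [sample_evidence(sid, call_sample(pu))
                     for sid, pu in cohort.pileups.items()]
        table = flag_oxog_samples(evidences)
        excluded = set(table.loc[table["excluded"], "sample_id"])
        injected = {sid for sid, ox in cohort.truth.oxog.items() if ox}
        hits += excluded == injected
    return hits / n_reps


def residual_variance_flagging_accuracy(n_reps: int = 20,
                                        n_clean: int = 35,
                                        n_noisy: int = 4,
                                        bins_per_chrom: int = 100,
                                        clean_sd: float = 0.1,
                                        inflation: float = 5.0,
                                        seed: int = 0) -> float:
    """Fraction of cohorts where exactly the noise-inflated samples flag.

    Per-sample profiles (two chromosomes of bins, with occasional genuine
    copy-number shifts) are CBS-segmented; the residual variance around
    segment means feeds the median + 3 MAD exclusion rule.
    """
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        variances = {}
        truth_noisy = set()
        order = rng.permutation(n_clean + n_noisy)
        for rank, idx in enumerate(order):
            sid = f"s{idx}"
            noisy = rank < n_noisy
            if noisy:
                truth_noisy.add(sid)
            sd = clean_sd * (inflation if noisy else 1.0)
            resid_sq = []
            for _ in range(2):  # two chromosomes
                x = rng.normal(0.0, sd, bins_per_chrom)
                if rng.random() < 0.5:  # a genuine segmental shift
                    s0 = int(rng.integers(0, bins_per_chrom - 20))
                    x[s0:s0 + 20] += rng.choice([-1, 1]) * 0.5
                segs = cbs.cbs_segment(x, seed=rng)
                segs = cbs.undo_splits(x, segs)
                for a, b in segs:
                    resid_sq.append((x[a:b] - np.mean(x[a:b])) ** 2)
            variances[sid] = float(np.mean(np.concatenate(resid_sq)))
        from .cna import residual_variance_qc

        table = residual_variance_qc(variances)
        flagged = set(table.loc[table["excluded"], "sample_id"])
        hits += flagged == truth_noisy
    return hits / n_reps
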
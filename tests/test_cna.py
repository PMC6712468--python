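"""Copy-ratio computation, binning, segment cleaning and sample QC."""

import numpy as np
import pandas as pd
import pytest

from pjflow.cna import (call_state, compute_copy_ratios,
                        filter_offtarget_and_refuse, make_bins, read_seg,
                        residual_variance, residual_variance_qc,
                        segment_sample, write_seg, SEG_COLUMNS)
from pjflow.intervals import TargetInterval


def bins_frame(rows):
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "on_target",
                                 "below_min"])


def test_copy_ratio_formula():
    bins = bins_frame([("1", 0, 100, True, False)] * 3)
    bins["start"] = [0, 100, 200]
    bins["end"] = [100, 200, 300]
    out = compute_copy_ratios(bins, [100, 300, 200], [100, 100, 100],
                              tumor_total=1000, normal_total=1000)
    assert out["log2"].iloc[0] == pytest.approx(0.0)
    assert out["log2"].iloc[1] == pytest.approx(np.log2(3))
    # doubling the tumor library size cancels in the normalization
    out2 = compute_copy_ratios(bins, [200, 600, 400], [100, 100, 100],
                               tumor_total=2000, normal_total=1000)
    assert np.allclose(out["log2"], out2["log2"])


def test_zero_depth_bins_marked_undefined():
    bins = bins_frame([("1", 0, 100, True, False),
                       ("1", 100, 200, True, False)])
    out = compute_copy_ratios(bins, [0, 50], [100, 100], 1000, 1000)
    assert not out["defined"].iloc[0]
    assert np.isnan(out["log2"].iloc[0])


def test_mismatched_bins_rejected():
    bins = bins_frame([("1", 0, 100, True, False)])
    with pytest.raises(ValueError):
        compute_copy_ratios(bins, [1, 2], [1], 10, 10)


def test_large_target_split_into_max_size_bins():
    out = make_bins([TargetInterval("1", 0, 250_000)])
    assert len(out) == 3
    assert ((out["end"] - out["start"]) <= 100_000).all()
    assert out["start"].iloc[0] == 0 and out["end"].iloc[-1] == 250_000


def test_short_target_kept_with_flag():
    out = make_bins([TargetInterval("1", 0, 50)])
    assert len(out) == 1
    assert bool(out["below_min"].iloc[0])


def test_bins_cover_exactly_the_targets():
    """Union of bins equals union of targets (interval arithmetic)."""
    rng = np.random.default_rng(2)
    pos = 0
    targets = []
    for _ in range(25):
        pos += int(rng.integers(200, 2000))
        length = int(rng.integers(60, 260_000))
        targets.append(TargetInterval("7", pos, pos + length))
        pos += length
    out = make_bins(targets)
    covered = [(r.start, r.end) for r in out.itertuples()]
    # bins are disjoint, in order, and re-fuse to the target list
    merged = []
    for s, e in covered:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    assert merged == [(t.start, t.end) for t in targets]


def seg_row(chrom, start, end, mean, sample="s", n=10):
    return (sample, chrom, start, end, n, mean, call_state(mean))


def test_offtarget_only_segment_removed():
    targets = [TargetInterval("1", 1000, 2000)]
    segs = pd.DataFrame([seg_row("1", 1200, 1800, 0.5),
                         seg_row("1", 5000, 6000, 0.5)],
                        columns=SEG_COLUMNS)
    out = filter_offtarget_and_refuse(segs, targets)
    assert len(out) == 1 and out["start"].iloc[0] == 1200


def test_equal_mean_neighbors_refused_and_idempotent():
    targets = [TargetInterval("1", 0, 10_000)]
    segs = pd.DataFrame([seg_row("1", 0, 500, 0.3),
                         seg_row("1", 500, 900, 0.3),
                         seg_row("1", 900, 1500, 0.0)],
                        columns=SEG_COLUMNS)
    once = filter_offtarget_and_refuse(segs, targets)
    assert len(once) == 2
    assert once["end"].iloc[0] == 900 and once["n_bins"].iloc[0] == 20
    twice = filter_offtarget_and_refuse(once, targets)
    pd.testing.assert_frame_equal(once, twice)


def test_states_flip_exactly_at_thresholds():
    assert call_state(0.2) == "neutral"
    assert call_state(0.2000001) == "amp"
    assert call_state(-0.2) == "neutral"
    assert call_state(-0.2000001) == "del"


def test_residual_variance_zero_when_bins_equal_means():
    bins = bins_frame([("1", i * 100, (i + 1) * 100, True, False)
                       for i in range(10)])
    bins["log2"] = [0.5] * 5 + [-0.3] * 5
    bins["defined"] = True
    segs = pd.DataFrame([seg_row("1", 0, 500, 0.5),
                         seg_row("1", 500, 1000, -0.3)],
                        columns=SEG_COLUMNS)
    assert residual_variance(bins, segs) == pytest.approx(0.0)


def test_residual_variance_matches_noise_moment():
    """Noise SD 0.1 over one segment gives variance ~ 0.01."""
    rng = np.random.default_rng(21)
    n = 2500
    bins = bins_frame([("1", i * 100, (i + 1) * 100, True, False)
                       for i in range(n)])
    x = rng.normal(0.0, 0.1, n)
    bins["log2"] = x
    bins["defined"] = True
    segs = pd.DataFrame([seg_row("1", 0, n * 100, float(np.mean(x)))],
                        columns=SEG_COLUMNS)
    rv = residual_variance(bins, segs)
    assert rv == pytest.approx(0.01, rel=0.2)


def test_noise_inflated_samples_flagged():
    rng = np.random.default_rng(30)
    variances = {f"clean{i}": float(rng.uniform(0.008, 0.012))
                 for i in range(20)}
    variances.update({f"noisy{i}": float(rng.uniform(0.2, 0.3))
                      for i in range(3)})
    table = residual_variance_qc(variances).set_index("sample_id")
    assert set(table.index[table["excluded"]]) == \
        {"noisy0", "noisy1", "noisy2"}


def test_segment_sample_partitions_defined_bins(small_cohort):
    sid = small_cohort.samples[0].sample_id
    tumor, normal = small_cohort.bin_counts[sid]
    ratios = compute_copy_ratios(small_cohort.bins, tumor, normal,
                                 tumor.sum(), normal.sum())
    segs = segment_sample(ratios, sid, seed=4)
    usable = ratios[ratios["defined"]]
    for chrom, grp in usable.groupby("chrom"):
        sub = segs[segs["chrom"] == chrom]
        assert sub["start"].iloc[0] == grp["start"].min()
        assert sub["end"].iloc[-1] == grp["end"].max()
        assert sub["n_bins"].sum() == len(grp)
        # stored means match recomputation from member bins
        for r in sub.itertuples():
            m = grp[(grp["start"] >= r.start) & (grp["end"] <= r.end)]
            assert r.mean_log2 == pytest.approx(m["log2"].mean(), abs=1e-9)


def test_seg_roundtrip(tmp_path, small_cohort):
    sid = small_cohort.samples[0].sample_id
    tumor, normal = small_cohort.bin_counts[sid]
    ratios = compute_copy_ratios(small_cohort.bins, tumor, normal,
                                 tumor.sum(), normal.sum())
    segs = segment_sample(ratios, sid, seed=4)
    path = tmp_path / "sample.seg"
    write_seg(path, segs)
    back = read_seg(path)
    assert back["start"].tolist() == segs["start"].tolist()
    assert back["end"].tolist() == segs["end"].tolist()
    assert np.allclose(back["mean_log2"], segs["mean_log2"], atol=5e-6)
    assert back["state"].tolist() == segs["state"].tolist()
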
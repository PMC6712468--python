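"""Copy-number pipeline: binning, copy ratios, segmentation, QC, SEG I/O.

Tumor/normal read counts over exome-derived bins are normalized into log2
copy ratios, segmented per chromosome by CBS with a 3-SD undo rule, then
cleaned: segments falling entirely outside capture targets are dropped
(off-target depth in exome data is untrustworthy) and consecutive segments
left with identical means are re-fused. Segments with mean log2 ratio
above 0.2 are called amplified, below -0.2 deleted. A per-sample residual
variance — the mean squared deviation of bin values from segment means —
screens out unstable samples before recurrence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cbs
from .intervals import TargetInterval, overlaps_any, validate_targets

AMP_THRESHOLD = 0.2
DEL_THRESHOLD = -0.2

BIN_COLUMNS = ["chrom", "start", "end", "on_target", "below_min"]


@dataclass(frozen=True)
class CnaConfig:
    min_bin_size: int = 100
    max_bin_size: int = 100_000
    alpha: float = 0.01
    n_perm: int = 1000
    undo_sd: float = 3.0
    amp_threshold: float = AMP_THRESHOLD
    del_threshold: float = DEL_THRESHOLD


def call_state(mean: float, amp: float = AMP_THRESHOLD,
               dele: float = DEL_THRESHOLD) -> str:
    if mean > amp:
        return "amp"
    if mean < dele:
        return "del"
    return "neutral"


def make_bins(targets: Sequence[TargetInterval], min_size: int = 100,
              max_size: int = 100_000) -> pd.DataFrame:
    """Split capture targets into bins of at most ``max_size`` bases.

    Targets are split into equal pieces; a trailing piece shorter than
    ``min_size`` is merged into its neighbor within the same target. A
    target shorter than ``min_size`` cannot be merged anywhere and is kept
    as a single bin flagged ``below_min``. Bins never span targets.
    """
    validate_targets(list(targets))
    rows = []
    for t in targets:
        length = len(t)
        n = max(1, -(-length // max_size))  # ceil division
        edges = np.linspace(t.start, t.end, n + 1).round().astype(int)
        pieces = list(zip(edges[:-1], edges[1:]))
        if len(pieces) > 1 and pieces[-1][1] - pieces[-1][0] < min_size:
            last = pieces.pop()
            pieces[-1] = (pieces[-1][0], last[1])
        for s, e in pieces:
            rows.append((t.chrom, int(s), int(e), True, e - s < min_size))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def compute_copy_ratios(bins: pd.DataFrame, tumor_counts: np.ndarray,
                        normal_counts: np.ndarray, tumor_total: float,
                        normal_total: float) -> pd.DataFrame:
    """Normalized per-bin log2 tumor/normal depth ratios.

    log2 ratio = log2((tumor_bin / normal_bin) * (normal_total / tumor_total));
    the total-read factor removes library-size differences. Bins with zero
    depth in either sample are marked undefined and excluded downstream.
    """
    tumor_counts = np.asarray(tumor_counts, float)
    normal_counts = np.asarray(normal_counts, float)
    if len(tumor_counts) != len(bins) or len(normal_counts) != len(bins):
        raise ValueError("bin count vectors do not match the bin table")
    if tumor_total <= 0 or normal_total <= 0:
        raise ValueError("total read counts must be positive")
    out = bins.copy()
    out["tumor"] = tumor_counts
    out["normal"] = normal_counts
    defined = (tumor_counts > 0) & (normal_counts > 0)
    log2 = np.full(len(bins), np.nan)
    log2[defined] = np.log2(tumor_counts[defined] / normal_counts[defined] *
                            (normal_total / tumor_total))
    out["log2"] = log2
    out["defined"] = defined
    return out


SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_bins", "mean_log2",
               "state"]


def segment_sample(ratio_bins: pd.DataFrame, sample_id: str,
                   config: CnaConfig | None = None,
                   seed: int | np.random.Generator | None = None
                   ) -> pd.DataFrame:
    """CBS-segment one sample's defined bins, chromosome by chromosome.

    Returns a SEG-like frame (0-based half-open coordinates) where
    segments partition each chromosome's defined bins in order.
    """
    config = config or CnaConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    usable = ratio_bins[ratio_bins["defined"]].reset_index(drop=True)
    rows = []
    for chrom, grp in usable.groupby("chrom", sort=True):
        x = grp["log2"].to_numpy()
        segs = cbs.cbs_segment(x, alpha=config.alpha, n_perm=config.n_perm,
                               seed=rng)
        segs = cbs.undo_splits(x, segs, sd_multiplier=config.undo_sd)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for s, e in segs:
            mean = float(np.mean(x[s:e]))
            rows.append((sample_id, chrom, int(starts[s]), int(ends[e - 1]),
                         e - s, mean,
                         call_state(mean, config.amp_threshold,
                                    config.del_threshold)))
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def filter_offtarget_and_refuse(segments: pd.DataFrame,
                                targets: Sequence[TargetInterval],
                                tol: float = 1e-9) -> pd.DataFrame:
    """Drop target-free segments, then merge equal-mean neighbors.

    A segment with zero overlap with every capture target can only have
    been generated from off-target coverage and is removed. Consecutive
    surviving segments on the same chromosome (same sample) whose means
    agree within ``tol`` are fused, their means combined with bin-count
    weights. Idempotent.
    """
    keep = segments[[overlaps_any(targets, r.chrom, r.start, r.end)
                     for r in segments.itertuples()]]
    rows: list[list] = []
    for r in keep.itertuples(index=False):
        r = list(r)
        if rows:
            prev = rows[-1]
            same_run = prev[0] == r[0] and prev[1] == r[1]
            if same_run and abs(prev[5] - r[5]) <= tol:
                w1, w2 = prev[4], r[4]
                prev[5] = (prev[5] * w1 + r[5] * w2) / (w1 + w2)
                prev[3] = r[3]
                prev[4] = w1 + w2
                prev[6] = call_state(prev[5])
                continue
        rows.append(r)
    return pd.DataFrame(rows, columns=segments.columns).reset_index(drop=True)


def residual_variance(ratio_bins: pd.DataFrame,
                      segments: pd.DataFrame) -> float:
    """Mean squared deviation of defined bin log2 ratios from segment means."""
    usable = ratio_bins[ratio_bins["defined"]]
    sq = []
    for r in segments.itertuples():
        m = usable[(usable["chrom"] == r.chrom) & (usable["start"] >= r.start)
                   & (usable["end"] <= r.end)]
        sq.append((m["log2"].to_numpy() - r.mean_log2) ** 2)
    if not sq:
        return 0.0
    return float(np.mean(np.concatenate(sq)))


def residual_variance_qc(variances: Mapping[str, float], k: float = 3.0,
                         cutoff: float | None = None,
                         mad_floor_fraction: float = 0.25) -> pd.DataFrame:
    """Flag samples whose residual variance is a cohort-level high outlier.

    Default rule: variance > cohort median + k*MAD. Variance estimates
    carry multiplicative sampling error (relative sd ~ sqrt(2/n_bins)), so
    the MAD is floored at ``mad_floor_fraction`` of the median to keep a
    tightly clustered cohort from flagging ordinary fluctuation. An
    absolute ``cutoff`` may be given instead.
    """
    if len(variances) < 3:
        raise ValueError("cohort-relative QC needs at least 3 samples")
    ids = list(variances)
    v = np.array([variances[s] for s in ids], float)
    if cutoff is None:
        med = float(np.median(v))
        mad = max(float(np.median(np.abs(v - med))),
                  mad_floor_fraction * med)
        cutoff = med + k * mad
    flags = v > cutoff
    return pd.DataFrame({"sample_id": ids, "residual_variance": v,
                         "excluded": flags})


def write_seg(path: str | Path, segments: pd.DataFrame) -> None:
    """Write segments as SEG (1-based inclusive coordinates)."""
    out = segments.copy()
    out["start"] = out["start"] + 1
    out = out.rename(columns={"sample_id": "ID", "chrom": "chrom",
                              "start": "loc.start", "end": "loc.end",
                              "n_bins": "num.mark", "mean_log2": "seg.mean"})
    cols = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"ID": "sample_id", "loc.start": "start",
                            "loc.end": "end", "num.mark": "n_bins",
                            "seg.mean": "mean_log2"})
    df["start"] = df["start"] - 1
    df["state"] = [call_state(m) for m in df["mean_log2"]]
    return df[SEG_COLUMNS]
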
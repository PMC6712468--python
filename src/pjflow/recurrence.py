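"""Recurrent copy-number region detection (GISTIC-style G-scores).

Segmented profiles are projected onto a common marker grid (bin
midpoints). For each marker the G-score sums, across samples, the
amplitude in excess of the calling threshold (0.2 in log2 units, with
per-sample amplitudes capped at |log2| <= 2 so a single extreme sample
cannot dominate). Significance comes from a permutation null in which
every sample's marker profile receives an independent random cyclic
shift — preserving its within-sample segmental structure while destroying
cross-sample alignment. Empirical p-values are pooled over all null
markers, corrected by Benjamini-Hochberg, and maximal runs of markers
with q below the threshold become candidate regions; the reported wide
("driver") interval extends around the peak until the G-score drops by
more than the null's high quantile (confidence 0.90 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class MarkerMatrix:
    """Per-sample log2 values on an ordered genome-wide marker grid."""

    chrom: np.ndarray  # (M,) marker chromosome
    pos: np.ndarray    # (M,) marker midpoint position
    values: np.ndarray  # (S, M) per-sample log2 ratio, missing -> 0
    sample_ids: list[str]

    def __post_init__(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(self.pos))):
            raise ValueError("markers must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "MarkerMatrix":
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return MarkerMatrix(self.chrom, self.pos, self.values[mask], ids)


def marker_matrix_from_seg(segments: pd.DataFrame,
                           bins: pd.DataFrame) -> MarkerMatrix:
    """Project SEG segments of all samples onto bin-midpoint markers."""
    b = bins.sort_values(["chrom", "start"], kind="mergesort")
    chrom = b["chrom"].to_numpy()
    pos = ((b["start"] + b["end"]) // 2).to_numpy()
    samples = sorted(segments["sample_id"].unique())
    X = np.zeros((len(samples), len(pos)))
    for si, sid in enumerate(samples):
        for r in segments[segments["sample_id"] == sid].itertuples():
            m = (chrom == r.chrom) & (pos >= r.start) & (pos < r.end)
            X[si, m] = r.mean_log2
    return MarkerMatrix(chrom, pos, X, samples)


def gscore(values: np.ndarray, direction: str, threshold: float = 0.2,
           cap: float = 2.0) -> np.ndarray:
    """Per-marker recurrence score: summed above-threshold amplitude."""
    x = np.clip(np.atleast_2d(values), -cap, cap)
    if direction == "amp":
        return np.maximum(x - threshold, 0.0).sum(axis=0)
    if direction == "del":
        return np.maximum(-threshold - x, 0.0).sum(axis=0)
    raise ValueError(f"direction must be 'amp' or 'del', got {direction!r}")


@dataclass
class NullDistribution:
    direction: str
    g_null: np.ndarray       # (n_perm, M) null G-scores
    max_g: np.ndarray = field(init=False)  # (n_perm,) per-permutation maxima
    _sorted_pool: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.max_g = self.g_null.max(axis=1)
        self._sorted_pool = np.sort(self.g_null, axis=None)

    def pvalues(self, g: np.ndarray) -> np.ndarray:
        """Pooled empirical p: fraction of all null marker G >= observed."""
        pool = self._sorted_pool
        n = pool.size
        ge = n - np.searchsorted(pool, g - 1e-12, side="left")
        return (1.0 + ge) / (1.0 + n)


def permutation_null(values: np.ndarray, direction: str, n_perm: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     threshold: float = 0.2, cap: float = 2.0
                     ) -> NullDistribution:
    """Cyclic-shift permutation null of the G-score profile.

    Each permutation applies an independent uniform cyclic shift to every
    sample's marker vector, keeping per-sample segmental runs intact.
    """
    X = np.atleast_2d(np.asarray(values, float))
    S, M = X.shape
    if M < 2:
        raise ValueError("need at least 2 markers")
    if S < 2:
        raise ValueError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    g_null = np.empty((n_perm, M))
    cols = np.arange(M)
    chunk = max(1, int(2e6 // (S * M)) or 1)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        shifts = rng.integers(0, M, size=(m, S))
        idx = (cols[None, None, :] - shifts[:, :, None]) % M
        shifted = np.take_along_axis(
            np.broadcast_to(X, (m, S, M)), idx, axis=2)
        for t in range(m):
            g_null[done + t] = gscore(shifted[t], direction, threshold, cap)
        done += m
    return NullDistribution(direction, g_null)


@dataclass
class RecurrentRegion:
    direction: str
    chrom: str
    peak_start: int
    peak_end: int
    wide_start: int
    wide_end: int
    g: float
    q: float
    altered: np.ndarray  # (S,) per-sample flag at the peak marker
    frequency: float = 0.0
    grade_frequencies: dict | None = None


def significant_regions(markers: MarkerMatrix, direction: str,
                        null: NullDistribution, q_threshold: float = 0.25,
                        confidence: float = 0.90, threshold: float = 0.2,
                        cap: float = 2.0,
                        grades: Sequence[int] | None = None
                        ) -> list[RecurrentRegion]:
    """Maximal runs of significant markers, with peak and driver bounds."""
    g = gscore(markers.values, direction, threshold, cap)
    p = null.pvalues(g)
    q = multipletests(p, method="fdr_bh")[1]
    sig = (q < q_threshold) & (g > 0)
    regions: list[RecurrentRegion] = []
    delta = float(np.quantile(null.max_g, confidence))
    M = markers.n_markers
    i = 0
    while i < M:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < M and sig[j + 1] and \
                markers.chrom[j + 1] == markers.chrom[i]:
            j += 1
        run = slice(i, j + 1)
        g_run = g[run]
        peak_rel = int(np.argmax(g_run))
        peak_g = float(g_run[peak_rel])
        # all markers tying the peak define the peak interval
        peak_ties = np.flatnonzero(g_run >= peak_g - 1e-12)
        lo, hi = peak_rel, peak_rel
        while lo > 0 and g_run[lo - 1] >= peak_g - delta:
            lo -= 1
        while hi < len(g_run) - 1 and g_run[hi + 1] >= peak_g - delta:
            hi += 1
        x_peak = markers.values[:, i + peak_rel]
        altered = x_peak > threshold if direction == "amp" \
            else x_peak < -threshold
        region = RecurrentRegion(
            direction, str(markers.chrom[i]),
            int(markers.pos[i + peak_ties[0]]),
            int(markers.pos[i + peak_ties[-1]]) + 1,
            int(markers.pos[i + lo]), int(markers.pos[i + hi]) + 1,
            peak_g, float(q[i + peak_rel]), altered,
            float(np.mean(altered)))
        if grades is not None:
            ga = np.asarray(grades)
            region.grade_frequencies = {
                int(gr): float(np.mean(altered[ga == gr]))
                for gr in np.unique(ga)}
        regions.append(region)
        i = j + 1
    regions.sort(key=lambda r: (r.q, r.chrom, r.peak_start))
    return regions


def find_recurrent_regions(markers: MarkerMatrix, direction: str,
                           n_perm: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           q_threshold: float = 0.25,
                           confidence: float = 0.90,
                           threshold: float = 0.2, cap: float = 2.0,
                           grades: Sequence[int] | None = None
                           ) -> list[RecurrentRegion]:
    null = permutation_null(markers.values, direction, n_perm, seed,
                            threshold, cap)
    return significant_regions(markers, direction, null, q_threshold,
                               confidence, threshold, cap, grades)


def per_grade_runs(markers: MarkerMatrix, grades: Sequence[int],
                   direction: str, benign_grades: tuple[int, ...] = (1,),
                   n_perm: int = 1000,
                   seed: int | None = None, **kwargs
                   ) -> dict[str, list[RecurrentRegion]]:
    """Run region detection on benign (LGD) and malignant (HGD+INC) subsets.

    A subset with fewer than 2 samples is skipped (empty result).
    """
    ga = np.asarray(grades)
    out: dict[str, list[RecurrentRegion]] = {}
    ss = np.random.SeedSequence(seed)
    for name, mask in (("benign", np.isin(ga, benign_grades)),
                       ("malignant", ~np.isin(ga, benign_grades))):
        sub_seed = np.random.default_rng(ss.spawn(1)[0])
        if mask.sum() < 2:
            out[name] = []
            continue
        out[name] = find_recurrent_regions(
            markers.subset(mask), direction, n_perm=n_perm, seed=sub_seed,
            grades=ga[mask], **kwargs)
    return out


def regions_to_frame(regions: Sequence[RecurrentRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {"direction": r.direction, "chrom": r.chrom,
               "peak_start": r.peak_start, "peak_end": r.peak_end,
               "wide_start": r.wide_start, "wide_end": r.wide_end,
               "g_score": r.g, "q_value": r.q, "frequency": r.frequency}
        if r.grade_frequencies:
            for gr, f in sorted(r.grade_frequencies.items()):
                row[f"freq_grade{gr}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
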
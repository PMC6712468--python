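"""Circular binary segmentation of log2 copy-ratio profiles.

Recursive change-point search: within the current stretch of bins, the
candidate split is the circular arc maximizing the mean-shift statistic

    T(i, j) = |mean(x[i:j]) - mean(rest)| * sqrt(k (n - k) / n),  k = j - i,

which orders splits identically to the two-sample t statistic (the pooled
SD is permutation-invariant and cancels). Significance comes from a
within-stretch permutation null: the split is accepted when fewer than
``alpha`` of ``n_perm`` shuffles reach the observed maximum, and the
search recurses into the resulting pieces. A separate pruning pass
(:func:`undo_splits`) merges adjacent segments whose means differ by less
than a multiple of the residual SD.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cbs_segment", "undo_splits", "max_arc_statistic",
           "segment_means", "residual_sd"]


def max_arc_statistic(x: np.ndarray, min_width: int = 2
                      ) -> tuple[float, int, int]:
    """Best circular-arc split of ``x``: (statistic, i, j).

    The arc is ``x[i:j]``; both the arc and its complement must hold at
    least ``min_width`` bins. Returns (0, 0, n) when no arc is admissible.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2 * min_width:
        return 0.0, 0, n
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    i_idx = np.arange(n + 1)
    # sums and lengths for all (i, j) pairs, j > i
    sums = S[None, :] - S[:, None]          # sums[i, j] = sum x[i:j]
    k = i_idx[None, :] - i_idx[:, None]     # arc lengths
    valid = (k >= min_width) & (k <= n - min_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(sums / k - (total - sums) / (n - k)) * \
            np.sqrt(k * (n - k) / n)
    stat[~valid] = -np.inf
    flat = np.argmax(stat)
    i, j = divmod(flat, n + 1)
    return float(stat[i, j]), int(i), int(j)


def _perm_max_stats(x: np.ndarray, n_perm: int, rng: np.random.Generator,
                    min_width: int) -> np.ndarray:
    """Null distribution of the max arc statistic under shuffling.

    For a fixed arc length k the statistic is an affine function of the
    arc sum, so each length is handled with one vectorized slice across
    all permutations; temporaries stay cache-sized.
    """
    n = len(x)
    total = float(np.sum(x))
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)).copy(), axis=1)
    S = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)],
                       axis=1)
    out = np.zeros(n_perm)
    for k in range(min_width, n - min_width + 1):
        scale = np.sqrt(k * (n - k) / n)
        # |mean_in - mean_out| rewritten around the arc sum
        a = scale * n / (k * (n - k))
        b = scale * total / (n - k)
        arc = S[:, k:] - S[:, :-k]
        stat = np.abs(a * arc - b).max(axis=1)
        np.maximum(out, stat, out=out)
    return out


def cbs_segment(x: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                seed: int | np.random.Generator | None = None,
                min_width: int = 2) -> list[tuple[int, int]]:
    """Segment a 1-D log2-ratio profile; returns bin-index ranges.

    The returned ``(start, end)`` half-open ranges partition ``range(len(x))``
    in order. A constant (or empty-variance) profile yields one segment.
    """
    x = np.asarray(x, float)
    if len(x) == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    breaks: set[int] = {0, len(x)}
    stack = [(0, len(x))]
    while stack:
        s, e = stack.pop()
        seg = x[s:e]
        if len(seg) < 2 * min_width or np.ptp(seg) == 0:
            continue
        stat, i, j = max_arc_statistic(seg, min_width)
        if stat <= 0:
            continue
        null = _perm_max_stats(seg, n_perm, rng, min_width)
        p = (1.0 + np.sum(null >= stat - 1e-12)) / (1.0 + n_perm)
        if p >= alpha:
            continue
        cuts = {s + i, s + j} - {s, e}
        if not cuts:
            continue
        breaks |= cuts
        pieces = sorted(breaks & set(range(s, e + 1)) | {s, e})
        for a, b in zip(pieces, pieces[1:]):
            stack.append((a, b))
    bounds = sorted(breaks)
    return list(zip(bounds, bounds[1:]))


def segment_means(x: np.ndarray, segments: list[tuple[int, int]]
                  ) -> np.ndarray:
    return np.array([np.mean(x[s:e]) for s, e in segments])


def residual_sd(x: np.ndarray, segments: list[tuple[int, int]]) -> float:
    """Pooled SD of bin deviations from their segment means (RMS)."""
    x = np.asarray(x, float)
    resid = np.concatenate([x[s:e] - np.mean(x[s:e]) for s, e in segments]) \
        if segments else np.array([])
    return float(np.sqrt(np.mean(resid ** 2))) if len(resid) else 0.0


def undo_splits(x: np.ndarray, segments: list[tuple[int, int]],
                sd_multiplier: float = 3.0) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means are closer than k residual SDs.

    The threshold is fixed from the input segmentation's residual SD;
    merging proceeds smallest-difference first and repeats until every
    adjacent pair differs by at least the threshold.
    """
    segs = list(segments)
    if len(segs) < 2:
        return segs
    x = np.asarray(x, float)
    thr = sd_multiplier * residual_sd(x, segs)
    while len(segs) > 1:
        means = segment_means(x, segs)
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] >= thr:
            break
        segs[k] = (segs[k][0], segs[k + 1][1])
        del segs[k + 1]
    return segs
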
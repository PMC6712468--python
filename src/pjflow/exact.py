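"""Exact tests on contingency tables.

Two tests drive the pipeline:

* the paired tumor/normal site test — a one-sided Fisher exact test for
  enrichment of the alternate allele in the tumor reads, evaluated as a
  hypergeometric tail;
* the 2xK (Freeman-Halton) exact test used for region-by-grade association,
  evaluated by full enumeration of tables with the observed margins under
  the minimum-likelihood two-sided criterion, with a seeded Monte-Carlo
  fallback for intractable margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

_REL_TOL = 1e-7  # tables within this relative likelihood count as "as extreme"


def fisher_test_site(tumor_alt: int, tumor_ref: int,
                     normal_alt: int, normal_ref: int,
                     alternative: str = "greater") -> float:
    """One-sided Fisher exact p for tumor alt-allele enrichment.

    Conditions on the margins of ``[[tumor_alt, tumor_ref],
    [normal_alt, normal_ref]]``: with N reads in total, K alt reads and a
    tumor depth of n, the p-value is ``P(X >= tumor_alt)`` for
    ``X ~ Hypergeometric(N, K, n)``. ``alternative="two-sided"`` gives the
    classical two-sided test instead.
    """
    counts = (tumor_alt, tumor_ref, normal_alt, normal_ref)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative counts {counts}")
    if tumor_alt + tumor_ref == 0 or normal_alt + normal_ref == 0:
        raise ValueError("tumor and normal depth must both be positive")
    if alternative == "two-sided":
        from scipy.stats import fisher_exact

        return float(fisher_exact([[tumor_alt, tumor_ref],
                                   [normal_alt, normal_ref]],
                                  alternative="two-sided")[1])
    if alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    N = sum(counts)
    K = tumor_alt + normal_alt
    n = tumor_alt + tumor_ref
    return float(hypergeom.sf(tumor_alt - 1, N, K, n))


@dataclass
class ExactTestResult:
    p: float
    method: str  # "enumeration" or "monte-carlo"
    se: float | None = None  # standard error of the MC estimate

    def __float__(self) -> float:
        return self.p


def _as_2xk(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if t.shape[0] != 2 and t.shape[1] == 2:
        t = t.T
    if t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2xK table with K>=2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return t


def _log_binom(n, k):
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2xk(table, max_enum: float = 1e7, n_mc: int = 1_000_000,
                     seed: int | None = None) -> ExactTestResult:
    """Two-sided exact test for a 2xK contingency table.

    Conditional on both margins, table probabilities are multivariate
    hypergeometric; the two-sided p-value is the total probability of
    tables no more likely than the one observed (the minimum-likelihood
    criterion, as in R's ``fisher.test``). Enumeration is exhaustive when
    the loose table-count bound is at most ``max_enum``; otherwise tables
    are sampled (``n_mc`` draws, seeded) and a standard error is reported.
    """
    t = _as_2xk(table)
    col = t.sum(axis=0)  # per-category totals
    r1 = int(t[0].sum())  # altered-row margin
    K = t.shape[1]
    # per-column log C(col_j, k) lookup
    logc = [_log_binom(int(c), np.arange(int(c) + 1)) for c in col]
    log_obs = sum(logc[j][t[0, j]] for j in range(K))
    log_cut = log_obs + np.log1p(_REL_TOL)
    log_total = _log_binom(int(col.sum()), r1)

    bound = np.prod([min(int(c), r1) + 1.0 for c in col])
    if bound <= max_enum:
        sel: list[float] = []
        suffix = np.concatenate([np.cumsum(col[::-1])[::-1], [0]])

        def rec(j: int, left: int, acc: float) -> None:
            if j == K - 1:
                if left <= col[j]:
                    lp = acc + logc[j][left]
                    if lp <= log_cut:
                        sel.append(lp)
                return
            lo = max(0, left - int(suffix[j + 1]))
            hi = min(int(col[j]), left)
            for a in range(lo, hi + 1):
                rec(j + 1, left - a, acc + logc[j][a])

        rec(0, r1, 0.0)
        p = float(np.exp(logsumexp(sel) - log_total))
        return ExactTestResult(min(p, 1.0), "enumeration")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col, r1, size=n_mc)
    lp = np.zeros(n_mc)
    for j in range(K):
        lp += logc[j][draws[:, j]]
    hits = lp <= log_cut
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return ExactTestResult(p, "monte-carlo", se)
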
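"""Cohort-level statistics: tumor fraction, burden-grade correlation,
region-grade association and co-occurrence.

Grades are encoded ordinally (LGD=1 < HGD=2 < INC=3); rank statistics are
invariant to any monotone recoding. The tumor-derived DNA fraction of a
pancreatic-juice sample is estimated as twice the median VAF of its
somatic calls — a clonal heterozygous diploid event in a sample of purity
p has expected VAF p/2 — and is only reported for samples with more than
10 calls, where the median is stable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .calling import MutationCall
from .exact import fisher_exact_2xk

GRADE_LABELS = {1: "LGD", 2: "HGD", 3: "INC"}
GRADE_CODES = {v: k for k, v in GRADE_LABELS.items()}

MIN_CALLS_FOR_FRACTION = 10  # strictly more than this many PASS calls


@dataclass
class SampleRecord:
    sample_id: str
    grade: int  # 1=LGD, 2=HGD, 3=INC
    sex: str = "NA"
    duct_type: str = "NA"  # branch / main / mix
    n_pass: int | None = None
    tumor_fraction: float | None = None
    region_flags: dict = field(default_factory=dict)
    tp53_mutation: bool = False
    oxog_excluded: bool = False
    cna_excluded: bool = False

    @property
    def grade_label(self) -> str:
        return GRADE_LABELS[self.grade]


def estimate_tumor_fraction(calls: Sequence[MutationCall],
                            min_calls: int = MIN_CALLS_FOR_FRACTION
                            ) -> float | None:
    """2 x median VAF of PASS calls, clipped to [0, 1]; None if too few."""
    vafs = [c.tumor_vaf for c in calls if c.passed]
    if len(vafs) <= min_calls:
        return None
    return float(np.clip(2.0 * np.median(vafs), 0.0, 1.0))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    denom = np.sqrt(np.sum((rx - rx.mean()) ** 2) *
                    np.sum((ry - ry.mean()) ** 2))
    if denom == 0:
        return float("nan")
    hits = 0
    total = 0
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(rxc, ryc[list(perm)]) / denom)
        hits += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


def spearman_burden_grade(grades: Sequence[int], burdens: Sequence[float]
                          ) -> tuple[float, float]:
    """Spearman correlation of mutation burden with histologic grade.

    Mid-ranks for ties; t-approximation p for n >= 10, exact permutation
    enumeration below that. Constant grades give (nan, nan).
    """
    g = np.asarray(grades, float)
    b = np.asarray(burdens, float)
    if len(g) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(g) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    rho, p = spearmanr(g, b)
    if len(g) < 10:
        p = _exact_spearman_p(g, b, rho)
    return float(rho), float(p)


def _pct(x: float) -> float:
    return float(Decimal(repr(100.0 * x)).quantize(Decimal("0.01"),
                                                   rounding=ROUND_HALF_UP))


def region_grade_association(region_flags: Mapping[str, Sequence[bool]],
                             grades: Sequence[int],
                             seed: int | None = None) -> pd.DataFrame:
    """Per-region 2xK grade table, per-grade frequencies, exact-test p.

    ``region_flags`` maps region name -> per-sample altered flags aligned
    with ``grades``. Regions altered in no sample get p = 1. Output sorted
    by p-value.
    """
    ga = np.asarray(grades)
    levels = sorted(np.unique(ga))
    rows = []
    for name, flags in region_flags.items():
        fa = np.asarray(flags, bool)
        table = [(int(np.sum(fa[ga == lv])), int(np.sum(~fa[ga == lv])))
                 for lv in levels]
        if fa.sum() == 0:
            p = 1.0
        else:
            p = fisher_exact_2xk(np.array(table).T, seed=seed).p
        row = {"region": name, "p_value": p}
        for lv, (alt, not_alt) in zip(levels, table):
            tot = alt + not_alt
            row[f"altered_{GRADE_LABELS.get(lv, lv)}"] = f"{alt}/{tot}"
            row[f"pct_{GRADE_LABELS.get(lv, lv)}"] = \
                _pct(alt / tot) if tot else 0.0
        rows.append(row)
    return pd.DataFrame(rows).sort_values("p_value", kind="mergesort") \
        .reset_index(drop=True)


def cooccurrence(flags_a: Sequence[bool], flags_b: Sequence[bool],
                 grades: Sequence[int] | None = None) -> dict:
    """Joint 2x2 counts of two per-sample events, optionally by grade."""
    a = np.asarray(flags_a, bool)
    b = np.asarray(flags_b, bool)
    if len(a) != len(b):
        raise ValueError("flag vectors differ in length")

    def counts(mask):
        return {"both": int(np.sum(a[mask] & b[mask])),
                "a_only": int(np.sum(a[mask] & ~b[mask])),
                "b_only": int(np.sum(~a[mask] & b[mask])),
                "neither": int(np.sum(~a[mask] & ~b[mask]))}

    out = {"overall": counts(np.ones(len(a), bool))}
    if grades is not None:
        ga = np.asarray(grades)
        out["by_grade"] = {GRADE_LABELS.get(int(lv), str(lv)):
                           counts(ga == lv) for lv in np.unique(ga)}
    return out


REPORT_SCHEMA_VERSION = "1.0"


def _round_sig(x, digits: int = 6):
    if isinstance(x, float):
        return float(f"{x:.{digits}g}")
    return x


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def cohort_report(samples: Sequence[SampleRecord],
                  class_counts: Mapping[str, int] | None = None,
                  region_association: pd.DataFrame | None = None,
                  cooccurrence_result: dict | None = None) -> dict:
    """Assemble the machine-readable cohort report.

    Burden/grade correlation and tumor-fraction summaries are computed
    from the sample records (QC-excluded samples are omitted from the
    statistics their exclusion concerns: OxoG exclusions from SNV-derived
    numbers, residual-variance exclusions from CNA-derived ones).
    """
    snv_ok = [s for s in samples if not s.oxog_excluded
              and s.n_pass is not None]
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_samples": len(samples),
        "n_snv_analyzed": len(snv_ok),
        "n_cna_analyzed": sum(1 for s in samples if not s.cna_excluded),
        "samples": [
            {"sample_id": s.sample_id, "grade": s.grade_label,
             "sex": s.sex, "duct_type": s.duct_type, "n_pass": s.n_pass,
             "tumor_fraction": s.tumor_fraction,
             "tp53_mutation": s.tp53_mutation,
             "oxog_excluded": s.oxog_excluded,
             "cna_excluded": s.cna_excluded,
             "region_flags": dict(s.region_flags)}
            for s in samples],
    }
    if len(snv_ok) >= 3 and len({s.grade for s in snv_ok}) > 1:
        rho, p = spearman_burden_grade([s.grade for s in snv_ok],
                                       [s.n_pass for s in snv_ok])
        report["burden_grade_spearman"] = {"rho": rho, "p": p}
    fractions = [s.tumor_fraction for s in snv_ok
                 if s.tumor_fraction is not None]
    if fractions:
        report["median_tumor_fraction"] = float(np.median(fractions))
        report["n_with_tumor_fraction"] = len(fractions)
    if class_counts is not None:
        total = sum(class_counts.values())
        report["consequence_classes"] = {
            k: {"count": v, "percent": _pct(v / total) if total else 0.0}
            for k, v in class_counts.items()}
    if region_association is not None:
        report["region_grade_association"] = \
            region_association.to_dict(orient="records")
    if cooccurrence_result is not None:
        report["tp53_17p_cooccurrence"] = cooccurrence_result
    return _clean(report)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
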
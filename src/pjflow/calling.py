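"""Paired tumor/normal somatic SNV/indel calling.

The caller applies read-level quality filters, then tests each candidate
alternate allele for tumor enrichment with a one-sided Fisher exact test,
and finally applies fixed allele-frequency and depth thresholds. Defaults
match deep cfDNA exome practice: minimum depth 8 (tumor and normal),
mapping quality >= 20, base quality >= 15, >= 3 supporting reads, tumor
VAF >= 0.05, normal VAF <= 0.1, Fisher p <= 0.05. Sites failing a filter
are retained with the failed filter named, in the order the filters are
applied: depth, supporting reads, tumor VAF, normal VAF, Fisher p.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_test_site
from .pileup import PileupSite, SamplePileup

CONSEQUENCE_CLASSES = ("missense", "nonsense", "frameshift_del",
                       "frameshift_ins", "splice", "inframe_del",
                       "silent", "unknown")


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 8
    min_mapq: float = 20.0
    min_baseq: float = 15.0
    min_variant_reads: int = 3
    min_tumor_af: float = 0.05
    max_normal_af: float = 0.1
    fisher_threshold: float = 0.05
    # depth filter applies to the tumor and the normal filtered depth alike
    depth_on_both: bool = True
    two_sided: bool = False

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_mapq, self.min_baseq,
               self.min_variant_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        for af in (self.min_tumor_af, self.max_normal_af):
            if not 0 <= af <= 1:
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class MutationCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    tumor_alt: int
    tumor_ref: int
    normal_alt: int
    normal_ref: int
    tumor_vaf: float
    normal_vaf: float
    p_value: float
    filter: str  # "PASS" or the name of the first failed filter
    consequence: str = "unknown"
    sample_id: str | None = None
    gene: str | None = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            not self.alt.startswith(("I:", "D:"))

    @property
    def passed(self) -> bool:
        return self.filter == "PASS"


def filter_reads(site: PileupSite, config: CallerConfig
                 ) -> tuple[Counter, Counter]:
    """Per-allele read counts after mapq/baseq filtering (tumor, normal)."""
    out = []
    for alleles, bq, mq in ((site.tumor_alleles, site.tumor_baseq,
                             site.tumor_mapq),
                            (site.normal_alleles, site.normal_baseq,
                             site.normal_mapq)):
        keep = (np.asarray(mq) >= config.min_mapq) & \
               (np.asarray(bq) >= config.min_baseq)
        out.append(Counter(np.asarray(alleles, dtype=object)[keep].tolist()))
    return out[0], out[1]


def call_site(site: PileupSite, config: CallerConfig) -> MutationCall | None:
    """Test the strongest alternate allele at one site.

    Returns None when no non-reference allele survives the read filters.
    At multi-allelic sites each alternate is tested independently against
    the reference and the lowest-p allele is reported.
    """
    t_counts, n_counts = filter_reads(site, config)
    t_ref = t_counts.get(site.ref, 0)
    n_ref = n_counts.get(site.ref, 0)
    alts = [a for a in t_counts if a != site.ref]
    if not alts:
        return None

    best = None
    for alt in alts:
        t_alt = t_counts[alt]
        n_alt = n_counts.get(alt, 0)
        t_pair = t_alt + t_ref
        n_pair = n_alt + n_ref
        if t_pair > 0 and n_pair > 0:
            alternative = "two-sided" if config.two_sided else "greater"
            p = fisher_test_site(t_alt, t_ref, n_alt, n_ref, alternative)
        else:
            p = 1.0
        if best is None or p < best[0]:
            best = (p, alt, t_alt, n_alt, t_pair, n_pair)

    p, alt, t_alt, n_alt, t_pair, n_pair = best
    t_vaf = t_alt / t_pair if t_pair else 0.0
    n_vaf = n_alt / n_pair if n_pair else 0.0

    # filter chain: first failure names the call's FILTER
    t_depth = sum(t_counts.values())
    n_depth = sum(n_counts.values())
    depth_ok = t_depth >= config.min_depth and \
        (not config.depth_on_both or n_depth >= config.min_depth)
    if not depth_ok:
        status = "depth_fail"
    elif t_alt < config.min_variant_reads:
        status = "min_variant_reads_fail"
    elif t_vaf < config.min_tumor_af:
        status = "tumor_af_fail"
    elif n_vaf > config.max_normal_af:
        status = "normal_af_fail"
    elif p > config.fisher_threshold:
        status = "fisher_fail"
    else:
        status = "PASS"

    return MutationCall(site.chrom, site.pos, site.ref, alt, site.context,
                        t_alt, t_pair - t_alt, n_alt, n_pair - n_alt,
                        t_vaf, n_vaf, p, status)


def call_sample(pileup: SamplePileup,
                config: CallerConfig | None = None) -> list[MutationCall]:
    """Call every site of a sample; output sorted by coordinate."""
    config = config or CallerConfig()
    if not pileup.is_sorted():
        raise ValueError(f"pileup for {pileup.sample_id} is not "
                         "coordinate-sorted")
    calls = []
    for site in pileup.sites:
        call = call_site(site, config)
        if call is not None:
            call.sample_id = pileup.sample_id
            calls.append(call)
    return calls


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def classify_and_count(calls: Iterable[MutationCall] | Mapping[str, int]
                       ) -> pd.DataFrame:
    """Consequence-class breakdown of PASS calls.

    Accepts either a list of calls (PASS calls are tallied by their
    consequence label, missing labels count as "unknown") or a ready
    mapping class -> count. Percentages of the total are rounded half-up
    to two decimals.
    """
    if isinstance(calls, Mapping):
        counts = dict(calls)
    else:
        counts = Counter()
        for c in calls:
            if c.passed:
                counts[c.consequence or "unknown"] += 1
        counts = dict(counts)
    total = sum(counts.values())
    rows = [(label, n, _round2(100.0 * n / total) if total else 0.0)
            for label, n in sorted(counts.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows, columns=["consequence", "count", "percent"])


def annotate_calls(calls: Sequence[MutationCall],
                   annotations: Mapping) -> None:
    """Attach consequence/gene labels from an external annotation map.

    ``annotations`` maps (chrom, pos, alt) -> (consequence, gene).
    Consequence prediction itself is out of scope; labels are carried
    through from the annotation source (or the simulation truth).
    """
    for c in calls:
        hit = annotations.get((c.chrom, c.pos, c.alt))
        if hit is not None:
            c.consequence, c.gene = hit


def burden(calls: Sequence[MutationCall]) -> int:
    """Number of PASS somatic calls (the per-sample mutation burden)."""
    return sum(1 for c in calls if c.passed)
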
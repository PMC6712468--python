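"""8-oxoguanine (OxoG) artifact QC.

Oxidative damage during library preparation produces spurious C>A (read as
G>T on the opposite strand) substitutions at low allele fraction, enriched
at the middle base of CCN trinucleotides. A sample heavily affected shows
three signatures at once: depressed median VAF of its calls, an excess of
CCN-context C>A calls (the oxidation score), and a mutation spectrum whose
mass concentrates in the C>A / 5'-C bins. Samples are excluded from SNV
statistics when at least ``n_required`` of these three evidences are
cohort-level outliers (median +/- k*MAD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import MutationCall
from .reference import revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_B = "ACGT"
CONTEXTS = tuple(l + "." + r for l in _B for r in _B)


def pyrimidine_strand(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Collapse a substitution onto the pyrimidine strand.

    Returns (substitution, trinucleotide context) with the mutated base as
    C or T; purine-reference events are reverse-complemented.
    """
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return f"{ref}>{alt}", context


@dataclass
class SpectrumProfile:
    """96-bin trinucleotide substitution spectrum (pyrimidine strand)."""

    counts: pd.Series  # MultiIndex (substitution, context)
    n_skipped: int = 0

    @classmethod
    def empty(cls) -> "SpectrumProfile":
        # context is the full trinucleotide, e.g. ACA for C>A flanked by A/A
        bins = [(sub, left + sub[0] + right)
                for sub in SUBSTITUTIONS for left in _B for right in _B]
        idx = pd.MultiIndex.from_tuples(bins,
                                        names=["substitution", "context"])
        return cls(pd.Series(0, index=idx, dtype=int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def signature_score(self) -> float:
        """Fraction of spectrum mass in C>A bins whose 5' base is C."""
        if self.total == 0:
            return 0.0
        mask = [(sub == "C>A" and ctx[0] == "C")
                for sub, ctx in self.counts.index]
        return float(self.counts[mask].sum() / self.total)


def build_spectrum(calls: Iterable[MutationCall]) -> SpectrumProfile:
    """Tally PASS SNVs into the 96 pyrimidine-strand bins.

    Non-SNV events (indels) are skipped and counted in ``n_skipped``.
    """
    prof = SpectrumProfile.empty()
    for c in calls:
        if not c.passed:
            continue
        if not c.is_snv:
            prof.n_skipped += 1
            continue
        sub, ctx = pyrimidine_strand(c.ref, c.alt, c.context)
        prof.counts.loc[(sub, ctx)] += 1
    return prof


def _is_ccn_ca(call: MutationCall) -> bool:
    sub, ctx = pyrimidine_strand(call.ref, call.alt, call.context)
    return sub == "C>A" and ctx[0] == "C"


def oxidation_score(calls: Iterable[MutationCall]) -> float:
    """Fraction of PASS SNVs that are CCN-context C>A (or G>T) events."""
    snvs = [c for c in calls if c.passed and c.is_snv]
    if not snvs:
        return 0.0
    return sum(_is_ccn_ca(c) for c in snvs) / len(snvs)


def median_vaf(calls: Iterable[MutationCall]) -> float:
    vafs = [c.tumor_vaf for c in calls if c.passed]
    return float(np.median(vafs)) if vafs else float("nan")


@dataclass
class OxoGEvidence:
    sample_id: str
    median_vaf: float
    oxidation_score: float
    signature_score: float
    low_vaf_flag: bool = False
    oxidation_flag: bool = False
    signature_flag: bool = False
    excluded: bool = False

    @property
    def n_evidences(self) -> int:
        return int(self.low_vaf_flag) + int(self.oxidation_flag) + \
            int(self.signature_flag)


def sample_evidence(sample_id: str,
                    calls: Sequence[MutationCall]) -> OxoGEvidence:
    spectrum = build_spectrum(calls)
    return OxoGEvidence(sample_id, median_vaf(calls), oxidation_score(calls),
                        spectrum.signature_score())


def flag_oxog_samples(evidences: Sequence[OxoGEvidence], k: float = 3.0,
                      n_required: int = 2, score_scale_floor: float = 0.1,
                      vaf_scale_floor: float = 0.02) -> pd.DataFrame:
    """Cohort-relative outlier flags and the combined exclusion decision.

    A sample is flagged on an evidence when it lies beyond k MADs from the
    cohort median in the direction contamination pushes it (VAF down,
    scores up); exclusion requires ``n_required`` of the three evidences.
    The MAD is floored (``*_scale_floor``) because the scores are
    fractions of small call counts: a sample with ~10 PASS SNVs moves in
    steps of ~0.1, so a cohort MAD below that granularity reflects
    discreteness, not spread, and genuine contamination pushes the scores
    far above any such floor.
    Degenerate all-identical cohorts therefore flag nothing. Flags are
    set in place on the evidence objects and returned as a table.
    """
    if len(evidences) < 3:
        raise ValueError("cohort-relative QC needs at least 3 samples")

    def mad(v, floor):
        raw = np.median(np.abs(v - np.median(v)))
        return max(float(raw), floor)

    vaf = np.array([e.median_vaf for e in evidences])
    oxi = np.array([e.oxidation_score for e in evidences])
    sig = np.array([e.signature_score for e in evidences])
    vaf_ok = ~np.isnan(vaf)
    vaf_med = np.median(vaf[vaf_ok]) if vaf_ok.any() else np.nan
    vaf_mad = mad(vaf[vaf_ok], vaf_scale_floor) if vaf_ok.any() else np.nan
    oxi_thr = np.median(oxi) + k * mad(oxi, score_scale_floor)
    sig_thr = np.median(sig) + k * mad(sig, score_scale_floor)

    for i, e in enumerate(evidences):
        e.low_vaf_flag = bool(vaf_ok[i] and
                              vaf[i] < vaf_med - k * vaf_mad)
        e.oxidation_flag = bool(oxi[i] > oxi_thr)
        e.signature_flag = bool(sig[i] > sig_thr)
        e.excluded = e.n_evidences >= n_required

    return pd.DataFrame(
        [(e.sample_id, e.median_vaf, e.oxidation_score, e.signature_score,
          e.low_vaf_flag, e.oxidation_flag, e.signature_flag, e.excluded)
         for e in evidences],
        columns=["sample_id", "median_vaf", "oxidation_score",
                 "signature_score", "low_vaf_flag", "oxidation_flag",
                 "signature_flag", "excluded"])
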
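"""VCF serialization of truth events and mutation calls (pysam-backed).

Atomic pileup alleles map onto VCF v4.2 as: SNVs directly; insertions
``I:SEQ`` as REF=anchor, ALT=anchor+SEQ; deletions ``D:SEQ`` as
REF=anchor+SEQ, ALT=anchor. Events are emitted left-anchored at the
pileup position (the generator produces minimal representations, no
normalization pass is applied).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pysam

from .calling import MutationCall

FILTER_NAMES = ("depth_fail", "min_variant_reads_fail", "tumor_af_fail",
                "normal_af_fail", "fisher_fail")


def vcf_alleles(ref_base: str, allele: str) -> tuple[str, str]:
    """(REF, ALT) for an atomic pileup allele anchored at ``ref_base``."""
    if allele.startswith("I:"):
        return ref_base, ref_base + allele[2:]
    if allele.startswith("D:"):
        return ref_base + allele[2:], ref_base
    return ref_base, allele


def atomic_allele(ref: str, alt: str) -> str:
    """Inverse of :func:`vcf_alleles`."""
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if len(alt) > len(ref) and alt.startswith(ref):
        return "I:" + alt[len(ref):]
    if len(ref) > len(alt) and ref.startswith(alt):
        return "D:" + ref[len(alt):]
    raise ValueError(f"cannot reduce {ref}->{alt} to an atomic allele")


def _header(contigs: dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, length in contigs.items():
        h.contigs.add(chrom, length=length)
    return h


def write_calls_vcf(path: str | Path, calls: Sequence[MutationCall],
                    contigs: dict[str, int]) -> None:
    h = _header(contigs)
    for name in FILTER_NAMES:
        h.filters.add(name, None, None, f"failed {name[:-5]} threshold")
    h.info.add("TALT", 1, "Integer", "Tumor alt read count (filtered)")
    h.info.add("TREF", 1, "Integer", "Tumor ref read count (filtered)")
    h.info.add("NALT", 1, "Integer", "Normal alt read count (filtered)")
    h.info.add("NREF", 1, "Integer", "Normal ref read count (filtered)")
    h.info.add("TVAF", 1, "Float", "Tumor variant allele frequency")
    h.info.add("NVAF", 1, "Float", "Normal variant allele frequency")
    h.info.add("FP", 1, "Float", "Fisher exact p-value (one-sided)")
    h.info.add("CLASS", 1, "String", "Consequence class label")
    h.info.add("CTX", 1, "String", "Reference trinucleotide context")
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for c in calls:
            ref, alt = vcf_alleles(c.ref, c.alt)
            rec = vf.new_record(contig=c.chrom, start=c.pos - 1,
                                alleles=(ref, alt))
            rec.info["TALT"] = c.tumor_alt
            rec.info["TREF"] = c.tumor_ref
            rec.info["NALT"] = c.normal_alt
            rec.info["NREF"] = c.normal_ref
            rec.info["TVAF"] = c.tumor_vaf
            rec.info["NVAF"] = c.normal_vaf
            rec.info["FP"] = c.p_value
            rec.info["CLASS"] = c.consequence
            rec.info["CTX"] = c.context
            if c.filter == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(c.filter)
            vf.write(rec)


def read_calls_vcf(path: str | Path,
                   sample_id: str | None = None) -> list[MutationCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = atomic_allele(rec.ref, rec.alts[0])
            ref = rec.ref[0]
            filt = list(rec.filter) or ["PASS"]
            calls.append(MutationCall(
                rec.contig, rec.pos, ref, alt,
                rec.info.get("CTX", "N" + ref + "N"),
                int(rec.info["TALT"]), int(rec.info["TREF"]),
                int(rec.info["NALT"]), int(rec.info["NREF"]),
                float(rec.info["TVAF"]), float(rec.info["NVAF"]),
                float(rec.info["FP"]), filt[0],
                rec.info.get("CLASS", "unknown"), sample_id))
    return calls
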
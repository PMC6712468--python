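"""Per-site paired tumor/normal pileups.

A :class:`PileupSite` carries the per-read observations (allele, base
quality, mapping quality) for both members of a tumor/normal pair at one
genomic position. Alleles are atomic strings:

* a single base (``"A"``) for a match or substitution,
* ``"I:SEQ"`` for an insertion of SEQ immediately after the position,
* ``"D:SEQ"`` for a deletion of SEQ starting at the next position.

There is no realignment; indel alleles are taken at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass
class PileupSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    context: str  # trinucleotide, middle base == ref
    tumor_alleles: np.ndarray
    tumor_baseq: np.ndarray
    tumor_mapq: np.ndarray
    normal_alleles: np.ndarray
    normal_baseq: np.ndarray
    normal_mapq: np.ndarray

    def __post_init__(self) -> None:
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError(
                f"context {self.context!r} does not match ref {self.ref!r} "
                f"at {self.chrom}:{self.pos}")

    @property
    def tumor_depth(self) -> int:
        return len(self.tumor_alleles)

    @property
    def normal_depth(self) -> int:
        return len(self.normal_alleles)


@dataclass
class SamplePileup:
    """All pileup sites of one sample, sorted by (chrom, pos)."""

    sample_id: str
    sites: list[PileupSite] = field(default_factory=list)

    def sort(self) -> None:
        self.sites.sort(key=lambda s: (s.chrom, s.pos))

    def is_sorted(self) -> bool:
        keys = [(s.chrom, s.pos) for s in self.sites]
        return keys == sorted(keys)

    def __len__(self) -> int:
        return len(self.sites)


_COLUMNS = ["chrom", "pos", "ref", "context", "role", "allele", "baseq", "mapq"]


def pileup_to_frame(pileup: SamplePileup) -> pd.DataFrame:
    """Flatten to one row per read (the fixture TSV dialect)."""
    rows = []
    for s in pileup.sites:
        for role, alleles, bq, mq in (
                ("tumor", s.tumor_alleles, s.tumor_baseq, s.tumor_mapq),
                ("normal", s.normal_alleles, s.normal_baseq, s.normal_mapq)):
            for a, b, m in zip(alleles, bq, mq):
                rows.append((s.chrom, s.pos, s.ref, s.context, role, a,
                             float(b), float(m)))
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_pileup(df: pd.DataFrame, sample_id: str) -> SamplePileup:
    sites = []
    for (chrom, pos), grp in df.groupby(["chrom", "pos"], sort=True):
        ref = grp["ref"].iloc[0]
        context = grp["context"].iloc[0]
        t = grp[grp["role"] == "tumor"]
        n = grp[grp["role"] == "normal"]
        sites.append(PileupSite(
            str(chrom), int(pos), ref, context,
            t["allele"].to_numpy(dtype=object), t["baseq"].to_numpy(float),
            t["mapq"].to_numpy(float),
            n["allele"].to_numpy(dtype=object), n["baseq"].to_numpy(float),
            n["mapq"].to_numpy(float)))
    pu = SamplePileup(sample_id, sites)
    pu.sort()
    return pu


def write_pileup_tsv(path: str | Path, pileup: SamplePileup) -> None:
    pileup_to_frame(pileup).to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")


def read_pileup_tsv(path: str | Path, sample_id: str | None = None) -> SamplePileup:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    if sample_id is None:
        sample_id = Path(path).stem
    return frame_to_pileup(df, sample_id)


def make_site(chrom: str, pos: int, ref: str, context: str,
              tumor: Iterable[tuple[str, float, float]],
              normal: Iterable[tuple[str, float, float]]) -> PileupSite:
    """Convenience constructor from (allele, baseq, mapq) triples."""
    def unpack(reads):
        reads = list(reads)
        if not reads:
            return (np.array([], dtype=object), np.array([]), np.array([]))
        a, b, m = zip(*reads)
        return (np.array(a, dtype=object), np.array(b, float), np.array(m, float))

    ta, tb, tm = unpack(tumor)
    na, nb, nm = unpack(normal)
    return PileupSite(chrom, pos, ref, context, ta, tb, tm, na, nb, nm)
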
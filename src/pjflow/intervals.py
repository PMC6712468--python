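"""Exome target intervals and BED I/O.

Coordinates are 0-based half-open throughout the library; conversion to
1-based dialects happens only at serialization boundaries (VCF, SEG).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True, order=True)
class TargetInterval:
    """A capture target: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def validate_targets(targets: Sequence[TargetInterval]) -> None:
    """Require targets sorted by (chrom, start) and non-overlapping per chromosome."""
    for a, b in zip(targets, targets[1:]):
        if a.chrom == b.chrom:
            if b.start < a.start:
                raise ValueError("targets are not sorted")
            if b.start < a.end:
                raise ValueError(f"overlapping targets {a} / {b}")


def read_bed(path: str | Path) -> list[TargetInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    targets = [TargetInterval(r.chrom, int(r.start), int(r.end))
               for r in df.itertuples()]
    targets.sort()
    validate_targets(targets)
    return targets


def write_bed(path: str | Path, targets: Iterable[TargetInterval]) -> None:
    df = pd.DataFrame([(t.chrom, t.start, t.end) for t in targets])
    df.to_csv(path, sep="\t", header=False, index=False)


def total_span(targets: Sequence[TargetInterval]) -> int:
    return sum(len(t) for t in targets)


def overlaps_any(targets: Sequence[TargetInterval], chrom: str,
                 start: int, end: int) -> bool:
    """True if [start, end) on chrom intersects at least one target.

    Linear scan; target lists at desk scale are a few thousand intervals.
    """
    return any(t.overlaps(chrom, start, end) for t in targets)
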
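"""Reference sequence access: synthetic genomes and FASTA-backed references.

The pipeline only ever needs single bases and trinucleotide contexts, so the
interface is deliberately tiny. Synthetic genomes are generated with a seeded
RNG; real references are served by pyfaidx.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_BASES = np.array(["A", "C", "G", "T"])
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class SyntheticReference:
    """An in-memory genome of i.i.d. bases with configurable GC content."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences

    @classmethod
    def generate(cls, chrom_sizes: dict[str, int], gc: float = 0.45,
                 seed: int | np.random.SeedSequence = 0) -> "SyntheticReference":
        rng = np.random.default_rng(seed)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs = {}
        for chrom, size in chrom_sizes.items():
            seqs[chrom] = "".join(_BASES[rng.choice(4, size=size, p=p)])
        return cls(seqs)

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        return self.sequences[chrom][pos - 1]

    def context(self, chrom: str, pos: int) -> str:
        """Trinucleotide context (5'->3') centred on 1-based ``pos``.

        Positions at a chromosome edge are padded with N.
        """
        seq = self.sequences[chrom]
        i = pos - 1
        left = seq[i - 1] if i > 0 else "N"
        right = seq[i + 1] if i + 1 < len(seq) else "N"
        return left + seq[i] + right

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


class FastaReference:
    """pyfaidx-backed reference with the same base/context interface."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def base(self, chrom: str, pos: int) -> str:
        return str(self._fa[chrom][pos - 1]).upper()

    def context(self, chrom: str, pos: int) -> str:
        n = len(self._fa[chrom])
        i = pos - 1
        left = str(self._fa[chrom][i - 1]).upper() if i > 0 else "N"
        right = str(self._fa[chrom][i + 1]).upper() if i + 1 < n else "N"
        return left + self.base(chrom, pos) + right


def load_reference(path: str | Path) -> SyntheticReference:
    """Read a (small) FASTA fully into memory as a SyntheticReference."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return SyntheticReference({name: str(fa[name][:]).upper()
                               for name in fa.keys()})
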
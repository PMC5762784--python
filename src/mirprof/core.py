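"""Shared containers for the small-RNA profiling pipeline.

The pipeline moves data through three in-memory shapes:

* :class:`SmallRNARead` — a single sequencing read (identifier, bases,
  Phred+33 quality string), the unit the cleaning stage consumes.
* :class:`MatureReference` — the named set of mature miRNA sequences that
  clean sequence tags are matched against.  Sequences are normalised to the
  DNA alphabet (U→T) on construction so all downstream matching works in a
  single alphabet.
* :class:`CountMatrix` — miRNA × library read counts together with the
  per-library clean-read totals that serve as the TPM denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

# Canonical Illumina small-RNA adapters.  These are configuration defaults,
# not assumptions baked into any algorithm: every stage that touches an
# adapter takes it as a parameter.
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` half away from zero to ``ndigits`` decimal places.

    Python's built-in ``round`` uses banker's rounding; published tables in
    this field are rounded half-up, so exact halves (e.g. 2.185) must go up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def display_ratio(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Ratio of two already-rounded table values, rounded half-up for display.

    The division is carried out in decimal arithmetic on the printed operand
    values so that quotients landing exactly on a half (48.07/22.00 = 2.185)
    round the way a published table rounds them, unaffected by binary
    floating-point representation error.
    """
    if denominator == 0:
        raise ZeroDivisionError("display_ratio denominator is zero")
    q = Decimal(1).scaleb(-ndigits)
    ratio = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SmallRNARead:
    """One small-RNA sequencing read.

    ``qual`` is stored as a Phred+33 ASCII string (the FASTQ on-disk
    encoding); :attr:`quals` exposes the integer scores.
    """

    read_id: str
    bases: str
    qual: str
    comment: str | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read with empty identifier")
        if len(self.bases) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qual)} quality values"
            )

    @property
    def quals(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]

    def mean_quality(self) -> float:
        if not self.qual:
            return 0.0
        return sum(self.qual.encode("ascii")) / len(self.qual) - 33.0

    def __len__(self) -> int:
        return len(self.bases)


class MatureReference:
    """Named set of mature miRNA sequences, the matching target.

    Sequences are upper-cased and U→T normalised on construction.  Identifiers
    must be unique and sequences pairwise distinct; the matcher relies on both.
    """

    def __init__(
        self,
        sequences: Mapping[str, str] | Iterable[tuple[str, str]],
        *,
        min_len: int = 18,
        max_len: int = 26,
    ) -> None:
        items = sequences.items() if isinstance(sequences, Mapping) else sequences
        normalised: dict[str, str] = {}
        seen: dict[str, str] = {}
        for name, seq in items:
            if not name:
                raise ValueError("reference entry with empty name")
            if name in normalised:
                raise ValueError(f"duplicate reference id {name!r}")
            s = seq.upper().replace("U", "T")
            bad = set(s) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"reference {name!r} contains non-ACGT characters after "
                    f"U->T normalisation: {sorted(bad)}"
                )
            if not (min_len <= len(s) <= max_len):
                raise ValueError(
                    f"reference {name!r} has length {len(s)}, outside "
                    f"[{min_len}, {max_len}]"
                )
            if s in seen:
                raise ValueError(
                    f"reference {name!r} duplicates the sequence of {seen[s]!r}"
                )
            seen[s] = name
            normalised[name] = s
        if not normalised:
            raise ValueError("empty mature reference")
        self._sequences = normalised

    @property
    def names(self) -> list[str]:
        return list(self._sequences)

    def items(self):
        return self._sequences.items()

    def __len__(self) -> int:
        return len(self._sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._sequences

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def by_length(self) -> dict[int, list[tuple[str, str]]]:
        """Reference entries bucketed by sequence length (id order preserved)."""
        out: dict[int, list[tuple[str, str]]] = {}
        for name, seq in self._sequences.items():
            out.setdefault(len(seq), []).append((name, seq))
        return out

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "MatureReference":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls(records, **kwargs)

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")
        return path


@dataclass
class CountMatrix:
    """miRNA × library integer counts plus per-library clean-read totals.

    ``lib_sizes`` is the TPM denominator: the total number of clean reads in
    each library, not the number of assigned reads.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate miRNA ids in count matrix: {dups}")
        if list(self.counts.columns) != list(self.lib_sizes.index):
            raise ValueError("count matrix columns and lib_sizes are misaligned")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        too_big = self.counts.sum(axis=0) > self.lib_sizes
        if too_big.any():
            libs = self.lib_sizes.index[too_big].tolist()
            raise ValueError(f"assigned counts exceed library size in {libs}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)
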
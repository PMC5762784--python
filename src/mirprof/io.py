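"""FASTQ/TSV input and output.

FASTQ parsing goes through :mod:`pysam` (htslib); everything tabular is
pandas.  The count-matrix TSV carries the per-library clean-read totals on a
``#lib_sizes`` line directly under the header so a matrix file is
self-contained for TPM normalisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

from .core import CountMatrix, SmallRNARead

LIB_SIZES_MARKER = "#lib_sizes"


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Yield reads from a (plain or gzipped) FASTQ file.

    Raises ``ValueError`` naming the offending record when a record has no
    quality string or mismatched base/quality lengths.
    """
    last: str | None = None
    with pysam.FastxFile(str(path)) as fh:
        iterator = iter(fh)
        while True:
            try:
                entry = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                where = f"after record {last!r}" if last else "at the first record"
                raise ValueError(
                    f"malformed FASTQ record in {path} ({where}): {exc}"
                ) from exc
            if entry.quality is None:
                raise ValueError(
                    f"malformed FASTQ record {entry.name!r} in {path}: "
                    "missing quality string"
                )
            last = entry.name
            yield SmallRNARead(
                read_id=entry.name,
                bases=(entry.sequence or "").upper(),
                qual=entry.quality,
                comment=entry.comment,
            )


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            header = f"@{r.read_id}" + (f" {r.comment}" if r.comment else "")
            fh.write(f"{header}\n{r.bases}\n+\n{r.qual}\n")
    return path


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        cols = "\t".join(matrix.libraries)
        fh.write(f"mirna_id\t{cols}\n")
        sizes = "\t".join(str(int(s)) for s in matrix.lib_sizes)
        fh.write(f"{LIB_SIZES_MARKER}\t{sizes}\n")
        matrix.counts.to_csv(fh, sep="\t", header=False)
    return path


def read_count_matrix(path: str | Path) -> CountMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sizes_line = fh.readline().rstrip("\n").split("\t")
        if sizes_line[0] != LIB_SIZES_MARKER:
            raise ValueError(
                f"{path}: expected a {LIB_SIZES_MARKER!r} line under the header"
            )
        libraries = header[1:]
        lib_sizes = pd.Series(
            [int(x) for x in sizes_line[1:]], index=libraries, name="lib_size"
        )
        counts = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    counts.columns = libraries
    counts.index.name = "mirna_id"
    return CountMatrix(counts=counts.astype(int), lib_sizes=lib_sizes)


def write_count_triplets(matrix: CountMatrix, path: str | Path) -> Path:
    """Sparse triplet form of the count matrix: one (mirna_id, library,
    count) line per non-zero cell, after a ``#lib_sizes`` preamble."""
    path = Path(path)
    with open(path, "w") as fh:
        for lib, size in matrix.lib_sizes.items():
            fh.write(f"{LIB_SIZES_MARKER}\t{lib}\t{int(size)}\n")
        fh.write("mirna_id\tlibrary\tcount\n")
        for lib in matrix.libraries:
            col = matrix.counts[lib]
            for mid, count in col[col > 0].items():
                fh.write(f"{mid}\t{lib}\t{int(count)}\n")
    return path


def write_de_table(de_table: pd.DataFrame, path: str | Path) -> Path:
    """Write a differential-expression table, index column ``mirna_id``."""
    path = Path(path)
    de_table.to_csv(path, sep="\t", index_label="mirna_id")
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mirna_id")


def write_length_distribution(
    distributions: Mapping[str, Mapping[int, float]], path: str | Path
) -> Path:
    """Long-format TSV of per-library insert-length percentages."""
    path = Path(path)
    rows = [
        {"library": lib, "length": length, "percent": pct}
        for lib, dist in distributions.items()
        for length, pct in sorted(dist.items())
    ]
    pd.DataFrame(rows, columns=["library", "length", "percent"]).to_csv(
        path, sep="\t", index=False
    )
    return path
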
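"""Tag collapsing and mismatch-tolerant assignment to mature miRNAs.

Clean inserts are collapsed to unique sequence tags, then each tag is
assigned to the mature miRNA of identical length within Hamming distance
``max_mismatch`` (default 2) on the sense strand — no indels, no partial
overlaps.  Ties on distance go to the lexicographically smallest miRNA id,
which makes assignment deterministic and independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, MatureReference, SmallRNARead


@dataclass
class TagSet:
    """Unique insert sequences and their read counts for one library."""

    library: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.tags.values())


@dataclass
class AssignmentTable:
    """Per-tag miRNA assignment: tag -> (mirna_id, mismatches)."""

    assignments: dict[str, tuple[str, int]] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)

    @property
    def assigned_tags(self) -> set[str]:
        return set(self.assignments)


def collapse_tags(inserts: Iterable[SmallRNARead], library: str = "lib") -> TagSet:
    """Collapse clean inserts into unique tags; counts partition the input."""
    counter: Counter[str] = Counter()
    for read in inserts:
        counter[read.bases] += 1
    return TagSet(library=library, tags=dict(counter))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_tags(
    tags: TagSet | Mapping[str, int] | Iterable[str],
    reference: MatureReference,
    max_mismatch: int = 2,
) -> AssignmentTable:
    """Assign tags to mature miRNAs by equal-length Hamming distance.

    A tag is assigned iff some reference sequence of identical length is
    within ``max_mismatch`` substitutions; the minimal-distance reference
    wins, ties broken by smallest miRNA id.  Tags containing N (or any
    non-ACGT character) never match at those positions.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if isinstance(tags, TagSet):
        tag_seqs: Iterable[str] = tags.tags.keys()
    elif isinstance(tags, Mapping):
        tag_seqs = tags.keys()
    else:
        tag_seqs = tags

    by_length = reference.by_length()
    exact: dict[str, str] = {}
    matrices: dict[int, tuple[list[str], np.ndarray]] = {}
    for length, entries in by_length.items():
        entries = sorted(entries)  # id order => argmin tie-break = smallest id
        ids = [name for name, _ in entries]
        mat = np.stack([_encode(seq) for _, seq in entries])
        matrices[length] = (ids, mat)
        for name, seq in entries:
            exact[seq] = name

    table = AssignmentTable()
    for tag in tag_seqs:
        hit = exact.get(tag)
        if hit is not None:
            table.assignments[tag] = (hit, 0)
            continue
        bucket = matrices.get(len(tag))
        if bucket is None or max_mismatch == 0:
            table.unassigned.add(tag)
            continue
        ids, mat = bucket
        dists = (mat != _encode(tag)).sum(axis=1)
        best = int(dists.argmin())
        if dists[best] <= max_mismatch:
            table.assignments[tag] = (ids[best], int(dists[best]))
        else:
            table.unassigned.add(tag)
    return table


def count_assigned(tagset: TagSet, assignment: AssignmentTable,
                   reference: MatureReference) -> pd.Series:
    """Read counts per reference miRNA for one library (zeros retained)."""
    counts = pd.Series(0, index=reference.names, name=tagset.library, dtype=int)
    for tag, (mirna_id, _) in assignment.assignments.items():
        counts[mirna_id] += tagset.tags.get(tag, 0)
    return counts


def build_count_matrix(
    tagsets: Sequence[TagSet],
    assignments: Sequence[AssignmentTable],
    lib_sizes: Mapping[str, int],
    reference: MatureReference,
) -> CountMatrix:
    """Assemble the miRNA × library count matrix.

    ``lib_sizes`` are the total clean reads per library (the TPM
    denominator), which may exceed the assigned totals.  Every reference
    miRNA is retained even if unobserved everywhere.
    """
    if len(tagsets) != len(assignments):
        raise ValueError("tagsets and assignments are not aligned")
    seen: set[str] = set()
    columns = {}
    for tagset, assignment in zip(tagsets, assignments):
        if tagset.library in seen:
            raise ValueError(f"library name collision: {tagset.library!r}")
        seen.add(tagset.library)
        if tagset.library not in lib_sizes:
            raise ValueError(f"no lib_size for library {tagset.library!r}")
        columns[tagset.library] = count_assigned(tagset, assignment, reference)
    counts = pd.DataFrame(columns)
    counts.index.name = "mirna_id"
    sizes = pd.Series({lib: int(lib_sizes[lib]) for lib in counts.columns},
                      name="lib_size")
    return CountMatrix(counts=counts, lib_sizes=sizes)
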
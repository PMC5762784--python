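"""Six-step small-RNA read cleaning and the insert-length summary.

Raw libraries are filtered read by read in a fixed step order; the first
failing step claims the read, so removal counts partition the input exactly:

1. ``low_quality``      — mean Phred below threshold
2. ``poly_n``           — N fraction above threshold
3. ``no_3p_adapter_or_insert`` — no 3'-adapter match, or adapter at position 0
   (no insert); surviving reads are trimmed to the insert here
4. ``5p_contaminant``   — insert begins with a 5'-adapter prefix
5. ``homopolymer``      — a single base dominates the insert (poly A/T/G/C)
6. ``too_short``        — trimmed insert shorter than ``min_insert_len``

Adapter detection is a best ungapped overlap scan: the leftmost position
where the adapter (or its prefix, for read-through into the adapter) matches
with at most ``adapter_max_mismatch_rate`` mismatches over at least
``adapter_min_overlap`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .core import DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P, SmallRNARead

STEP_ORDER = (
    "low_quality",
    "poly_n",
    "no_3p_adapter_or_insert",
    "5p_contaminant",
    "homopolymer",
    "too_short",
)


@dataclass
class CleaningConfig:
    min_insert_len: int = 18
    mean_quality_min: float = 20.0
    max_n_fraction: float = 0.05
    homopolymer_fraction: float = 0.8
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_min_overlap: int = 6
    adapter_max_mismatch_rate: float = 0.1
    # When False, reads in which no 3'-adapter match is found are kept whole
    # as their own insert instead of being removed.  Needed to re-clean
    # already-trimmed inserts (which no longer carry an adapter) without
    # losing them; raw-library cleaning keeps the default True.
    require_3p_adapter: bool = True

    def __post_init__(self) -> None:
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        for name in ("max_n_fraction", "homopolymer_fraction",
                     "adapter_max_mismatch_rate"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.adapter_3p or not self.adapter_5p:
            raise ValueError("adapters must be non-empty")
        if self.adapter_min_overlap < 1:
            raise ValueError("adapter_min_overlap must be >= 1")


@dataclass
class CleaningStats:
    """Read accounting: input == clean + sum of per-step removals."""

    input_count: int = 0
    removed_per_step: dict[str, int] = field(
        default_factory=lambda: {step: 0 for step in STEP_ORDER}
    )
    clean_count: int = 0

    def validate(self) -> None:
        total = self.clean_count + sum(self.removed_per_step.values())
        if total != self.input_count:
            raise AssertionError(
                f"cleaning stats do not conserve reads: input={self.input_count} "
                f"accounted={total}"
            )

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_per_step": dict(self.removed_per_step),
            "clean_count": self.clean_count,
        }


def find_3p_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> int | None:
    """Return the leftmost adapter start position, or None if absent.

    At candidate position ``i`` the window compared is
    ``seq[i : i + min(len(adapter), len(seq) - i)]`` against the adapter
    prefix of the same length (read-through means only an adapter prefix fits
    before the read ends).  A window qualifies when its mismatch count is at
    most ``floor(max_mismatch_rate * overlap)``.
    """
    n, a = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(a, n - i)
        allowed = int(max_mismatch_rate * overlap)
        mismatches = 0
        ok = True
        for x, y in zip(seq[i:i + overlap], adapter):
            if x != y:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return i
    return None


def _has_5p_contaminant(insert: str, adapter_5p: str) -> bool:
    # insert begins with an >= 8 nt prefix of the 5' adapter at <= 1 mismatch
    k = 8
    if len(insert) < k or len(adapter_5p) < k:
        return False
    mismatches = sum(1 for x, y in zip(insert[:k], adapter_5p[:k]) if x != y)
    return mismatches <= 1


def _is_homopolymer(insert: str, fraction: float) -> bool:
    if not insert:
        return False
    top = max(insert.count(b) for b in "ACGT")
    return top / len(insert) >= fraction


def clean_read(
    read: SmallRNARead, config: CleaningConfig
) -> tuple[SmallRNARead | None, str | None]:
    """Clean one read: returns (trimmed insert, None) or (None, failing step)."""
    if read.mean_quality() < config.mean_quality_min:
        return None, "low_quality"
    if read.bases.count("N") / max(len(read.bases), 1) > config.max_n_fraction:
        return None, "poly_n"

    pos = find_3p_adapter(
        read.bases,
        config.adapter_3p,
        config.adapter_min_overlap,
        config.adapter_max_mismatch_rate,
    )
    if pos is None:
        if config.require_3p_adapter:
            return None, "no_3p_adapter_or_insert"
        insert, qual = read.bases, read.qual
    elif pos == 0:
        return None, "no_3p_adapter_or_insert"  # adapter dimer: empty insert
    else:
        insert, qual = read.bases[:pos], read.qual[:pos]

    if _has_5p_contaminant(insert, config.adapter_5p):
        return None, "5p_contaminant"
    if _is_homopolymer(insert, config.homopolymer_fraction):
        return None, "homopolymer"
    if len(insert) < config.min_insert_len:
        return None, "too_short"
    return replace(read, bases=insert, qual=qual), None


def clean_library(
    reads: Iterable[SmallRNARead], config: CleaningConfig | None = None
) -> tuple[list[SmallRNARead], CleaningStats]:
    """Apply the six cleaning steps to a read stream.

    Returns the surviving adapter-trimmed inserts and per-step removal
    counts.  An empty input yields an empty output and all-zero stats.
    """
    config = config or CleaningConfig()
    stats = CleaningStats()
    clean: list[SmallRNARead] = []
    for read in reads:
        stats.input_count += 1
        insert, step = clean_read(read, config)
        if insert is None:
            stats.removed_per_step[step] += 1
        else:
            clean.append(insert)
    stats.clean_count = len(clean)
    stats.validate()
    return clean, stats


def length_distribution(
    inserts: Iterable[SmallRNARead], max_length: int = 30
) -> dict[int, float]:
    """Insert-length histogram in percent; lengths > ``max_length`` pool into
    the ``max_length`` bin (a ">= 30 nt" bin by default)."""
    counts: dict[int, int] = {}
    total = 0
    for r in inserts:
        total += 1
        bin_ = min(len(r), max_length)
        counts[bin_] = counts.get(bin_, 0) + 1
    if total == 0:
        raise ValueError("length_distribution requires at least one read")
    return {length: 100.0 * c / total for length, c in sorted(counts.items())}
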
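"""End-to-end orchestration: FASTQ libraries in, DE table and report out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io
from .cleaning import CleaningConfig, CleaningStats, clean_library, length_distribution
from .core import CountMatrix, MatureReference
from .de import (
    DEThresholds,
    GroupSpec,
    differential_expression,
    tpm_normalize,
)
from .quantify import build_count_matrix, collapse_tags, match_tags


@dataclass
class QuantificationResult:
    count_matrix: CountMatrix
    cleaning_stats: dict[str, CleaningStats]
    length_distributions: dict[str, dict[int, float]]


@dataclass
class AnalysisResult:
    count_matrix: CountMatrix
    tpm: pd.DataFrame
    de_table: pd.DataFrame
    cleaning_stats: dict[str, CleaningStats]
    length_distributions: dict[str, dict[int, float]]


def quantify_libraries(
    fastq_paths: Mapping[str, str | Path],
    reference: MatureReference,
    cleaning_config: CleaningConfig | None = None,
    max_mismatch: int = 2,
) -> QuantificationResult:
    """Clean, collapse and assign each library; assemble the count matrix.

    Library sizes are the clean-read totals of each library.
    """
    cleaning_config = cleaning_config or CleaningConfig()
    tagsets, assignments, lib_sizes = [], [], {}
    stats_by_lib: dict[str, CleaningStats] = {}
    dists: dict[str, dict[int, float]] = {}
    for lib, path in fastq_paths.items():
        clean, stats = clean_library(io.read_fastq(path), cleaning_config)
        stats_by_lib[lib] = stats
        if clean:
            dists[lib] = length_distribution(clean)
        tagset = collapse_tags(clean, library=lib)
        tagsets.append(tagset)
        assignments.append(match_tags(tagset, reference, max_mismatch))
        lib_sizes[lib] = stats.clean_count
    matrix = build_count_matrix(tagsets, assignments, lib_sizes, reference)
    return QuantificationResult(matrix, stats_by_lib, dists)


def run_analysis(
    fastq_paths: Mapping[str, str | Path],
    reference: MatureReference,
    spec: GroupSpec,
    thresholds: DEThresholds | None = None,
    cleaning_config: CleaningConfig | None = None,
    max_mismatch: int = 2,
) -> AnalysisResult:
    """Full pipeline: cleaning, quantification, TPM and DE calling."""
    quant = quantify_libraries(fastq_paths, reference, cleaning_config, max_mismatch)
    de_table = differential_expression(quant.count_matrix, spec, thresholds)
    return AnalysisResult(
        count_matrix=quant.count_matrix,
        tpm=tpm_normalize(quant.count_matrix),
        de_table=de_table,
        cleaning_stats=quant.cleaning_stats,
        length_distributions=quant.length_distributions,
    )
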
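"""TPM normalisation, group-averaged fold change, testing and DE calling.

The procedure mirrors a pooled-group small-RNA comparison:

* ``TPM = count * 1e6 / lib_size`` per library, with the library size being
  its total clean reads;
* the treatment summary is the unweighted mean TPM over the treatment
  libraries (L1..L6), the control summary the mean over control libraries;
* fold change is ``group_tpm / ck_tpm`` on the ratio scale, substituting a
  0.01 pseudo-TPM for either side when it is exactly zero;
* per-miRNA significance comes from a two-sided Fisher's exact test on the
  pooled group counts, Benjamini–Hochberg adjusted across miRNAs;
* a miRNA is called UP when ``max(group_tpm, ck_tpm) > min_tpm``,
  ``adj_p < max_adj_p`` and ``fold_change > fc_up`` (DOWN symmetrically with
  ``fold_change < fc_down``), all inequalities strict and evaluated on
  unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix

UP = "UP"
DOWN = "DOWN"
NS = "NS"


@dataclass
class GroupSpec:
    """Which libraries form the control (CK) and treatment groups."""

    control_libs: list[str]
    treatment_libs: list[str]

    def __post_init__(self) -> None:
        if not self.control_libs or not self.treatment_libs:
            raise ValueError("both groups must be non-empty")
        overlap = set(self.control_libs) & set(self.treatment_libs)
        if overlap:
            raise ValueError(f"libraries in both groups: {sorted(overlap)}")

    def validate_against(self, columns: Sequence[str]) -> None:
        missing = (set(self.control_libs) | set(self.treatment_libs)) - set(columns)
        if missing:
            raise ValueError(f"group libraries absent from matrix: {sorted(missing)}")


@dataclass
class DEThresholds:
    """Filter criteria for DE calling (ratio-scale fold-change bounds)."""

    min_tpm: float = 30.0
    max_adj_p: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    pseudo_tpm: float = 0.01

    def __post_init__(self) -> None:
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if not 0 < self.max_adj_p < 1:
            raise ValueError("max_adj_p must be in (0, 1)")
        if self.pseudo_tpm <= 0:
            raise ValueError("pseudo_tpm must be > 0")


def tpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Tags-per-million: ``count * 1e6 / lib_size`` per library.

    Zero counts stay exactly zero; the pseudo-count enters only in ratio
    computation downstream.
    """
    if (matrix.lib_sizes <= 0).any():
        bad = matrix.lib_sizes.index[matrix.lib_sizes <= 0].tolist()
        raise ValueError(f"library size must be > 0 (offenders: {bad})")
    return matrix.counts * 1e6 / matrix.lib_sizes


def group_mean_tpm(tpm: pd.DataFrame, spec: GroupSpec) -> pd.DataFrame:
    """Per-miRNA ``group_tpm`` (treatment mean) and ``ck_tpm`` (control mean)."""
    spec.validate_against(tpm.columns)
    return pd.DataFrame({
        "group_tpm": tpm[spec.treatment_libs].mean(axis=1),
        "ck_tpm": tpm[spec.control_libs].mean(axis=1),
    })


def fold_change(group_tpm: float, ck_tpm: float, pseudo_tpm: float = 0.01) -> float:
    """Ratio of group to control TPM with zero values replaced by the pseudo-TPM."""
    if group_tpm < 0 or ck_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    if pseudo_tpm <= 0:
        raise ValueError("pseudo_tpm must be > 0")
    numerator = group_tpm if group_tpm > 0 else pseudo_tpm
    denominator = ck_tpm if ck_tpm > 0 else pseudo_tpm
    return numerator / denominator


def _fold_change_vec(means: pd.DataFrame, pseudo_tpm: float) -> pd.Series:
    num = means["group_tpm"].where(means["group_tpm"] > 0, pseudo_tpm)
    den = means["ck_tpm"].where(means["ck_tpm"] > 0, pseudo_tpm)
    return num / den


def test_counts(matrix: CountMatrix, spec: GroupSpec) -> pd.Series:
    """Two-sided Fisher's exact p-value per miRNA on pooled group counts.

    The 2×2 table opposes (pooled treatment count, remaining treatment reads)
    to (pooled control count, remaining control reads).  Both pooled counts
    zero gives p = 1.
    """
    spec.validate_against(matrix.libraries)
    t_count = matrix.counts[spec.treatment_libs].sum(axis=1)
    c_count = matrix.counts[spec.control_libs].sum(axis=1)
    t_size = int(matrix.lib_sizes[spec.treatment_libs].sum())
    c_size = int(matrix.lib_sizes[spec.control_libs].sum())
    pvals = {}
    for mid in matrix.mirna_ids:
        a, c = int(t_count[mid]), int(c_count[mid])
        if a == 0 and c == 0:
            pvals[mid] = 1.0
            continue
        _, p = stats.fisher_exact([[a, t_size - a], [c, c_size - c]],
                                  alternative="two-sided")
        pvals[mid] = min(float(p), 1.0)
    return pd.Series(pvals, name="raw_p")


def adjust_bh(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to <= 1."""
    p = np.asarray(list(raw_p), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() and not np.isclose(p[p <= 0], 0).all():
        raise ValueError("p-values must be in (0, 1]")
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def call_de(
    means: pd.DataFrame,
    raw_p: pd.Series,
    adj_p: pd.Series,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Apply the filter criteria and return the per-miRNA DE table.

    ``means`` must carry ``group_tpm``/``ck_tpm`` columns; ``raw_p`` and
    ``adj_p`` must cover exactly the same miRNAs.  The expression floor
    passes when either group exceeds ``min_tpm``.
    """
    thresholds = thresholds or DEThresholds()
    ids = means.index
    for name, series in (("raw_p", raw_p), ("adj_p", adj_p)):
        if set(series.index) != set(ids):
            raise ValueError(f"{name} ids do not match the TPM summary")
    fc = _fold_change_vec(means, thresholds.pseudo_tpm)
    expressed = np.maximum(means["group_tpm"], means["ck_tpm"]) > thresholds.min_tpm
    significant = adj_p.reindex(ids) < thresholds.max_adj_p
    direction = pd.Series(NS, index=ids, name="direction")
    direction[expressed & significant & (fc > thresholds.fc_up)] = UP
    direction[expressed & significant & (fc < thresholds.fc_down)] = DOWN
    table = pd.DataFrame({
        "group_tpm": means["group_tpm"],
        "ck_tpm": means["ck_tpm"],
        "fold_change": fc,
        "raw_p": raw_p.reindex(ids),
        "adj_p": adj_p.reindex(ids),
        "direction": direction,
    })
    table.index.name = "mirna_id"
    return table


def differential_expression(
    matrix: CountMatrix,
    spec: GroupSpec,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Full DE procedure on a count matrix: TPM → means → test → BH → calls."""
    thresholds = thresholds or DEThresholds()
    tpm = tpm_normalize(matrix)
    means = group_mean_tpm(tpm, spec)
    raw_p = test_counts(matrix, spec)
    adj = pd.Series(adjust_bh(raw_p.to_numpy()), index=raw_p.index, name="adj_p")
    return call_de(means, raw_p, adj, thresholds)


def summarize_calls(de_table: pd.DataFrame, n_detected: int | None = None) -> dict:
    """Call tallies; with ``n_detected``, also the no-difference count."""
    up = int((de_table["direction"] == UP).sum())
    down = int((de_table["direction"] == DOWN).sum())
    out = {"up": up, "down": down, "total_de": up + down,
           "ns": int((de_table["direction"] == NS).sum())}
    if n_detected is not None:
        out["unchanged"] = n_detected - out["total_de"]
    return out
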
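"""Synthetic small-RNA experiment generator.

Emulates the study design the analysis assumes: one wild-type control
library (CK) and six treatment libraries (L1..L6) of 36 nt single-end reads
whose inserts are dominated by 21 nt and 24 nt small RNAs.  Each
miRNA-derived read is a mature sequence (with optional per-base substitution
errors) read through into the 3' adapter and truncated to the machine read
length.  Libraries share a log-normal baseline abundance profile; a spike
table multiplies selected miRNAs' expected abundance in every treatment
library by a known fold change, giving ground truth for recovery tests.

Five junk classes are injected at configurable fractions, each designed to
be claimed by exactly one cleaning step under the default cleaning
configuration:

* ``poly_n``         — reads with an N fraction above 5% (N bases at Q2)
* ``homopolymer``    — poly-A/T/G/C inserts
* ``short_fragment`` — inserts of 8–17 nt, below the 18 nt floor
* ``adapter_dimer``  — adapter at position 0, i.e. no insert
* ``unassignable``   — random sequence carrying no 3'-adapter match

All randomness flows from ``SimConfig.seed`` through a
:class:`numpy.random.SeedSequence` tree, so identical configurations produce
byte-identical FASTQ files.  :func:`simulate_counts` draws the *same*
per-library count realisation as :func:`generate_experiment` without
materialising reads, which makes deep multi-seed studies of the downstream
statistics cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cleaning import find_3p_adapter
from .core import (
    DEFAULT_ADAPTER_3P,
    DEFAULT_ADAPTER_5P,
    CountMatrix,
    MatureReference,
)
from .enrichment import AnnotationSet

#: Insert-length sampling weights with the two modes (21 nt, 24 nt) that
#: dominate plant seed small-RNA libraries.
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 0.02, 19: 0.03, 20: 0.08, 21: 0.30, 22: 0.10,
    23: 0.07, 24: 0.32, 25: 0.05, 26: 0.03,
}

CONTAMINANT_CLASSES = (
    "poly_n", "homopolymer", "short_fragment", "adapter_dimer", "unassignable",
)

#: Which cleaning step (see :mod:`mirprof.cleaning`) claims each junk class
#: under the default cleaning configuration.
CONTAMINANT_STEP = {
    "poly_n": "poly_n",
    "homopolymer": "homopolymer",
    "short_fragment": "too_short",
    "adapter_dimer": "no_3p_adapter_or_insert",
    "unassignable": "no_3p_adapter_or_insert",
}

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_fractions() -> dict[str, float]:
    return {
        "poly_n": 0.005,
        "homopolymer": 0.005,
        "short_fragment": 0.015,
        "adapter_dimer": 0.005,
        "unassignable": 0.01,
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    The defaults describe the desk-scale study emulated throughout the test
    suite: 7 libraries (1 control + 6 treatment) of 200,000 reads each, ~4%
    junk, log-normal abundance over 300 reference miRNAs, and a 0.5% per-base
    substitution error rate.
    """

    n_mirnas: int = 300
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    n_control: int = 1
    n_treatment: int = 6
    reads_per_library: int = 200_000
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.5
    spike_table: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.005
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    read_length: int = 36
    contaminant_fractions: dict[str, float] = field(default_factory=_default_fractions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        _validate_length_weights(self.length_weights)
        if self.n_control < 1 or self.n_treatment < 1:
            raise ValueError("need at least one control and one treatment library")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be a positive integer")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        unknown = set(self.contaminant_fractions) - set(CONTAMINANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown contaminant classes: {sorted(unknown)}")
        for cls, f in self.contaminant_fractions.items():
            if not 0 <= f < 1:
                raise ValueError(f"contaminant fraction {cls}={f} outside [0, 1)")
        if sum(self.contaminant_fractions.values()) >= 1:
            raise ValueError("contaminant fractions must sum to < 1")
        for mid, fc in self.spike_table.items():
            if fc <= 0:
                raise ValueError(f"spike fold change for {mid} must be > 0")
        if self.read_length < 18:
            raise ValueError("read_length must be >= 18")

    @property
    def n_libraries(self) -> int:
        return self.n_control + self.n_treatment

    @property
    def control_libraries(self) -> list[str]:
        if self.n_control == 1:
            return ["CK"]
        return [f"CK{i + 1}" for i in range(self.n_control)]

    @property
    def treatment_libraries(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_treatment)]

    @property
    def library_names(self) -> list[str]:
        return self.control_libraries + self.treatment_libraries


@dataclass
class GroundTruth:
    """Simulator truth for recovery tests.

    ``true_abundance`` holds the expected miRNA-derived read count per
    library (real-valued); ``realized_counts`` the multinomial draw actually
    emitted.  ``true_fold_change`` maps every reference miRNA to its
    treatment-group fold change (1.0 when unspiked).
    """

    true_abundance: pd.DataFrame
    realized_counts: pd.DataFrame
    true_fold_change: dict[str, float]
    contaminant_counts: pd.DataFrame

    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "true_abundance": outdir / "true_abundance.tsv",
            "realized_counts": outdir / "realized_counts.tsv",
            "true_fold_change": outdir / "true_fold_change.tsv",
            "contaminant_counts": outdir / "contaminant_counts.tsv",
        }
        self.true_abundance.to_csv(paths["true_abundance"], sep="\t",
                                   index_label="mirna_id")
        self.realized_counts.to_csv(paths["realized_counts"], sep="\t",
                                    index_label="mirna_id")
        pd.Series(self.true_fold_change, name="fold_change").to_csv(
            paths["true_fold_change"], sep="\t", index_label="mirna_id")
        self.contaminant_counts.to_csv(paths["contaminant_counts"], sep="\t",
                                       index_label="class")
        return paths


@dataclass
class ExperimentOutput:
    fastq_paths: dict[str, Path]
    truth: GroundTruth
    config: SimConfig


def _validate_length_weights(weights: Mapping[int, float]) -> None:
    if not weights:
        raise ValueError("length_weights is empty")
    bad = [k for k in weights if not (isinstance(k, int) and 18 <= k <= 26)]
    if bad:
        raise ValueError(f"length_weights keys must be integers in 18..26: {bad}")
    if any(v < 0 for v in weights.values()):
        raise ValueError("length_weights must be non-negative")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"length_weights must sum to 1 (got {total})")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def generate_reference(
    n_mirnas: int,
    length_weights: Mapping[int, float] | None = None,
    seed: int = 0,
) -> MatureReference:
    """Draw ``n_mirnas`` uniquely named, pairwise-distinct mature sequences.

    Lengths are sampled from ``length_weights`` (default: bimodal at 21 and
    24 nt); bases are uniform over ACGT.  Deterministic for a fixed seed.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    weights = dict(length_weights) if length_weights else dict(DEFAULT_LENGTH_WEIGHTS)
    _validate_length_weights(weights)
    lengths = sorted(k for k, v in weights.items() if v > 0)
    capacity = sum(4 ** L for L in lengths)
    if n_mirnas > capacity:
        raise ValueError(
            f"cannot draw {n_mirnas} distinct sequences from lengths {lengths}"
        )
    rng = np.random.default_rng(seed)
    probs = np.array([weights[L] for L in lengths], dtype=float)
    probs /= probs.sum()
    drawn_lengths = rng.choice(lengths, size=n_mirnas, p=probs)
    seen: set[str] = set()
    entries: list[tuple[str, str]] = []
    for i, L in enumerate(drawn_lengths):
        seq = _random_seq(rng, int(L))
        while seq in seen:
            seq = _random_seq(rng, int(L))
        seen.add(seq)
        entries.append((f"miR-sim-{i + 1:04d}", seq))
    return MatureReference(entries)


def baseline_abundance(reference: MatureReference, config: SimConfig) -> pd.Series:
    """Log-normal baseline abundance weights shared by all libraries.

    ``length_weights`` is a *read*-level sampling probability: within each
    insert-length class the raw log-normal draws are rescaled so the class
    totals follow the configured weights, which keeps the emitted length
    histogram bimodal at 21/24 nt regardless of which individual miRNAs
    dominate.  Lengths absent from ``length_weights`` keep their raw draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    w = rng.lognormal(config.abundance_logmean, config.abundance_logsd,
                      size=len(reference))
    series = pd.Series(w, index=reference.names, name="abundance")
    lengths = pd.Series({name: len(seq) for name, seq in reference.items()})
    for length, ids in lengths.groupby(lengths).groups.items():
        weight = config.length_weights.get(int(length))
        if weight is not None and weight > 0:
            series[ids] *= weight / series[ids].sum()
    return series


def baseline_tpm(reference: MatureReference, config: SimConfig) -> pd.Series:
    """Expected control-library TPM implied by the baseline abundances."""
    w = baseline_abundance(reference, config)
    return 1e6 * w / w.sum()


def default_spike_table(
    reference: MatureReference,
    config: SimConfig,
    n_up: int = 5,
    n_down: int = 5,
    fc_up: float = 4.0,
    fc_down: float = 0.25,
    min_tpm: float = 100.0,
) -> dict[str, float]:
    """Choose well-expressed miRNAs to spike with known group fold changes.

    Candidates are miRNAs whose baseline TPM exceeds ``min_tpm``; the pick is
    deterministic given ``config.seed``.
    """
    tpm = baseline_tpm(reference, config)
    candidates = sorted(tpm.index[tpm > min_tpm])
    need = n_up + n_down
    if len(candidates) < need:
        raise ValueError(
            f"only {len(candidates)} miRNAs exceed baseline TPM {min_tpm}; "
            f"cannot spike {need}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    chosen = [str(mid) for mid in rng.choice(candidates, size=need, replace=False)]
    return {**{m: fc_up for m in chosen[:n_up]},
            **{m: fc_down for m in chosen[n_up:]}}


def _contaminant_counts(config: SimConfig) -> dict[str, int]:
    return {
        cls: int(round(config.contaminant_fractions.get(cls, 0.0)
                       * config.reads_per_library))
        for cls in CONTAMINANT_CLASSES
    }


def _expected_setup(reference: MatureReference, config: SimConfig):
    """Shared scaffolding: abundances, fold changes, per-library proportions."""
    for mid in config.spike_table:
        if mid not in reference:
            raise ValueError(f"spike id {mid!r} is not in the reference")
    ids = reference.names
    weights = baseline_abundance(reference, config).to_numpy()
    fold = {mid: float(config.spike_table.get(mid, 1.0)) for mid in ids}
    fc_vec = np.array([fold[m] for m in ids])
    contam = _contaminant_counts(config)
    n_mirna_reads = config.reads_per_library - sum(contam.values())
    if n_mirna_reads < 1:
        raise ValueError("contaminant fractions leave no miRNA-derived reads")
    probs = {}
    for lib in config.library_names:
        w = weights * fc_vec if lib in config.treatment_libraries else weights
        probs[lib] = w / w.sum()
    return ids, fold, contam, n_mirna_reads, probs


def simulate_counts(
    reference: MatureReference, config: SimConfig
) -> tuple[CountMatrix, GroundTruth]:
    """Draw the per-library miRNA count realisation without writing reads.

    Uses the same random stream as :func:`generate_experiment`, so for a
    given configuration the realised counts are identical to what a full
    FASTQ round-trip would produce at the source.  Library sizes are the
    miRNA-derived read totals (what survives cleaning when every junk read
    is removed).
    """
    ids, fold, contam, n_mirna_reads, probs = _expected_setup(reference, config)
    ss = np.random.SeedSequence([config.seed, 1])
    children = ss.spawn(config.n_libraries)
    expected = {}
    realized = {}
    for child, lib in zip(children, config.library_names):
        rng = np.random.default_rng(child)
        expected[lib] = n_mirna_reads * probs[lib]
        realized[lib] = rng.multinomial(n_mirna_reads, probs[lib])
    exp_df = pd.DataFrame(expected, index=ids)
    real_df = pd.DataFrame(realized, index=ids)
    contam_df = pd.DataFrame(
        {lib: contam for lib in config.library_names},
        index=list(CONTAMINANT_CLASSES),
    )
    truth = GroundTruth(
        true_abundance=exp_df,
        realized_counts=real_df,
        true_fold_change=fold,
        contaminant_counts=contam_df,
    )
    lib_sizes = pd.Series(
        {lib: n_mirna_reads for lib in config.library_names}, name="lib_size"
    )
    matrix = CountMatrix(counts=real_df, lib_sizes=lib_sizes)
    return matrix, truth


def _poly_n_read(rng, read_length, qual_row) -> tuple[str, str]:
    seq = np.frombuffer(_random_seq(rng, read_length).encode(), dtype=np.uint8).copy()
    n_n = int(rng.integers(4, 9))
    pos = rng.choice(read_length, size=n_n, replace=False)
    seq[pos] = ord("N")
    qual = qual_row.copy()
    qual[pos] = 2 + 33  # N bases carry Q2, as basecallers emit them
    return seq.tobytes().decode("ascii"), qual.tobytes().decode("ascii")


def _apply_errors(template: str, insert_len: int, k: int, rng) -> str:
    pos = rng.choice(insert_len, size=k, replace=False)
    chars = list(template)
    for p in pos:
        alternatives = [b for b in _BASES if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def generate_experiment(
    reference: MatureReference,
    config: SimConfig,
    outdir: str | Path,
    write_truth: bool = True,
) -> ExperimentOutput:
    """Write one FASTQ file per library plus ground-truth TSVs.

    Every read is exactly ``config.read_length`` bases.  miRNA-derived reads
    are ``insert + 3' adapter`` (cycled) truncated to the read length, with
    substitution errors confined to the insert; inserts at or above the read
    length are emitted truncated with no adapter.  Read headers carry a
    ``source=`` comment naming the originating miRNA or junk class so emitted
    reads can be tallied against the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids, fold, contam, n_mirna_reads, probs = _expected_setup(reference, config)
    read_len = config.read_length
    pad = config.adapter_3p * (1 + read_len // len(config.adapter_3p))
    templates = []
    ins_lens = []
    for mid in ids:
        seq = reference[mid]
        ins_lens.append(min(len(seq), read_len))
        templates.append((seq + pad)[:read_len])
    ins_lens_arr = np.array(ins_lens)

    n_classes = len(CONTAMINANT_CLASSES)
    class_code = {cls: len(ids) + i for i, cls in enumerate(CONTAMINANT_CLASSES)}
    class_name = {v: k for k, v in class_code.items()}

    ss = np.random.SeedSequence([config.seed, 1])
    children = ss.spawn(config.n_libraries)
    expected = {}
    realized = {}
    fastq_paths: dict[str, Path] = {}

    for child, lib in zip(children, config.library_names):
        rng = np.random.default_rng(child)
        expected[lib] = n_mirna_reads * probs[lib]
        counts = rng.multinomial(n_mirna_reads, probs[lib])
        realized[lib] = counts

        codes = np.concatenate(
            [np.repeat(np.arange(len(ids)), counts)]
            + [np.full(contam[cls], class_code[cls]) for cls in CONTAMINANT_CLASSES]
        )
        codes = rng.permutation(codes)
        total = len(codes)
        qmat = (rng.integers(30, 41, size=(total, read_len)) + 33).astype(np.uint8)
        is_mirna = codes < len(ids)
        per_read_ins = np.where(is_mirna, ins_lens_arr[np.minimum(codes, len(ids) - 1)], 0)
        if config.error_rate > 0:
            err_k = rng.binomial(per_read_ins, config.error_rate)
        else:
            err_k = np.zeros(total, dtype=int)

        path = outdir / f"{lib}.fastq"
        fastq_paths[lib] = path
        with open(path, "w") as fh:
            for i in range(total):
                code = int(codes[i])
                qual = qmat[i].tobytes().decode("ascii")
                if code < len(ids):
                    source = ids[code]
                    bases = templates[code]
                    if err_k[i]:
                        bases = _apply_errors(bases, int(per_read_ins[i]),
                                              int(err_k[i]), rng)
                else:
                    cls = class_name[code]
                    source = cls
                    if cls == "poly_n":
                        bases, qual = _poly_n_read(rng, read_len, qmat[i])
                    elif cls == "homopolymer":
                        base = _BASES[int(rng.integers(0, 4))]
                        L = int(rng.integers(18, 27))
                        bases = (base * L + pad)[:read_len]
                    elif cls == "short_fragment":
                        L = int(rng.integers(8, 18))
                        bases = (_random_seq(rng, L) + pad)[:read_len]
                    elif cls == "adapter_dimer":
                        bases = pad[:read_len]
                    else:  # unassignable: random, guaranteed adapter-free
                        bases = _random_seq(rng, read_len)
                        while find_3p_adapter(bases, config.adapter_3p) is not None:
                            bases = _random_seq(rng, read_len)
                fh.write(f"@{lib}.{i + 1} source={source}\n{bases}\n+\n{qual}\n")

    exp_df = pd.DataFrame(expected, index=ids)
    real_df = pd.DataFrame({lib: realized[lib] for lib in config.library_names},
                           index=ids)
    contam_df = pd.DataFrame({lib: contam for lib in config.library_names},
                             index=list(CONTAMINANT_CLASSES))
    truth = GroundTruth(
        true_abundance=exp_df,
        realized_counts=real_df,
        true_fold_change=fold,
        contaminant_counts=contam_df,
    )
    if write_truth:
        truth.to_tsv(outdir / "truth")
    return ExperimentOutput(fastq_paths=fastq_paths, truth=truth, config=config)


def generate_annotations(
    mirna_ids: Sequence[str],
    n_genes: int = 400,
    n_terms: int = 60,
    seed: int = 0,
    targets_per_mirna: tuple[int, int] = (3, 12),
    terms_per_gene: tuple[int, int] = (1, 4),
    planted_terms: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, set[str]], AnnotationSet]:
    """Random miRNA→target and gene→GO-term tables for the enrichment stage.

    ``planted_terms`` maps a term id to miRNAs whose predicted targets get
    that term with high probability (0.7), planting a detectable enrichment
    signal against the random background.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene-{i + 1:04d}" for i in range(n_genes)]
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    targets: dict[str, set[str]] = {}
    for mid in mirna_ids:
        k = int(rng.integers(targets_per_mirna[0], targets_per_mirna[1] + 1))
        targets[mid] = set(rng.choice(genes, size=min(k, n_genes), replace=False))
    gene_terms: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        gene_terms[g] = set(rng.choice(terms, size=min(k, n_terms), replace=False))
    if planted_terms:
        for term, mids in planted_terms.items():
            pool = set().union(*(targets.get(m, set()) for m in mids))
            for g in sorted(pool):
                if rng.random() < 0.7:
                    gene_terms.setdefault(g, set()).add(term)
    annotation = AnnotationSet(target_to_terms=gene_terms, universe=set(genes))
    return targets, annotation
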
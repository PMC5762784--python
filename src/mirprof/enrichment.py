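"""Hypergeometric GO-term enrichment over predicted miRNA targets.

Target prediction itself is consumed as input (two TSV tables: miRNA→target
gene and gene→GO term); the statistic is the upper-tail hypergeometric
probability of seeing at least ``k`` annotated genes among the ``n``
selected, given ``K`` annotated genes in a universe of ``N``, with
Benjamini–Hochberg adjustment across all tested terms.  GO terms are flat
labels here — no ontology-graph propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .de import adjust_bh

ENRICHMENT_COLUMNS = ["term_id", "k", "K", "n", "N", "raw_p", "adj_p"]


@dataclass
class AnnotationSet:
    """gene → GO-term sets plus the gene universe.

    The universe defaults to the annotated genes but may be any superset
    (e.g. all genes in the genome annotation).
    """

    target_to_terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        stray = set(self.target_to_terms) - self.universe
        if stray:
            raise ValueError(
                f"annotated genes outside the universe: {sorted(stray)[:5]}"
            )
        for gene, terms in self.target_to_terms.items():
            if any(not t for t in terms):
                raise ValueError(f"empty GO term id on gene {gene!r}")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "AnnotationSet":
        """Read a two-column (gene_id, go_term) TSV, one pair per line."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "go_term"], dtype=str, comment="#")
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(df["gene_id"], df["go_term"]):
            mapping.setdefault(gene, set()).add(term)
        uni = set(universe) if universe is not None else set(mapping)
        return cls(target_to_terms=mapping, universe=uni)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for gene in sorted(self.target_to_terms):
                for term in sorted(self.target_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")
        return path

    def term_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for gene, terms in self.target_to_terms.items():
            for term in terms:
                members.setdefault(term, set()).add(gene)
        return members


def read_target_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (mirna_id, gene_id) target-prediction TSV."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["mirna_id", "gene_id"], dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for mid, gene in zip(df["mirna_id"], df["gene_id"]):
        out.setdefault(mid, set()).add(gene)
    return out


def targets_of(mirna_ids: Iterable[str],
               mirna_to_targets: Mapping[str, Iterable[str]]) -> set[str]:
    """Union of predicted target genes of the given miRNAs."""
    selected: set[str] = set()
    for mid in mirna_ids:
        selected.update(mirna_to_targets.get(mid, ()))
    return selected


def enrich(selected_genes: Iterable[str], annotation: AnnotationSet) -> pd.DataFrame:
    """Test every annotated term for over-representation in the selection.

    Returns one row per term with ``K >= 1``:
    ``raw_p = P(X >= k | N, K, n)`` (hypergeometric upper tail) and BH
    ``adj_p``, sorted ascending by ``(adj_p, raw_p, term_id)``.
    """
    selected = set(selected_genes)
    if not selected:
        raise ValueError("selected gene set is empty")
    outside = selected - annotation.universe
    if outside:
        raise ValueError(
            f"selected genes outside the universe: {sorted(outside)}"
        )
    members = annotation.term_members()
    n = len(selected)
    N = len(annotation.universe)
    rows = []
    for term in sorted(members):
        genes = members[term]
        K = len(genes)
        k = len(genes & selected)
        raw_p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "raw_p": min(raw_p, 1.0)})
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df["adj_p"] = adjust_bh(df["raw_p"].to_numpy())
    df = df.sort_values(["adj_p", "raw_p", "term_id"], kind="mergesort")
    return df.reset_index(drop=True)


def top_terms(rows: pd.DataFrame, k: int = 40) -> pd.DataFrame:
    """First ``min(k, len(rows))`` terms of an enrichment report."""
    if k <= 0:
        raise ValueError("k must be a positive integer")
    return rows.head(k).reset_index(drop=True)
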
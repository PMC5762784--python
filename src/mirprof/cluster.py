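"""Log2-ratio heatmap matrix, hierarchical row ordering, and report output.

For every DE miRNA the heatmap value in a treatment library is
``log2(TPM_line / TPM_CK)`` (pseudo-TPM substituted for zeros), with the
control column pinned to 0 so the wild type is the visual reference point.
Rows are ordered by agglomerative clustering (SciPy linkage); rows are put
in canonical (miRNA-id) order before clustering so the report is invariant
to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cleaning import CleaningStats
from .de import DOWN, UP, GroupSpec
from .io import write_de_table, write_length_distribution

LINKAGES = ("average", "complete", "single")
METRICS = ("euclidean", "correlation")


@dataclass
class HeatmapMatrix:
    """DE-miRNA × library matrix of log2 TPM ratios; CK column is all zeros."""

    values: pd.DataFrame
    ck_column: str


@dataclass
class RowClustering:
    order: list[int]
    newick: str
    linkage_matrix: np.ndarray | None


def log2_ratio_matrix(
    tpm: pd.DataFrame,
    de_table: pd.DataFrame,
    spec: GroupSpec,
    pseudo_tpm: float = 0.01,
) -> HeatmapMatrix:
    """Build the heatmap matrix over the UP/DOWN miRNAs of ``de_table``.

    The control reference is the mean TPM over ``spec.control_libs`` (a
    single-control design just uses that library); each treatment library
    contributes ``log2((tpm or pseudo) / (ck or pseudo))``.
    """
    spec.validate_against(tpm.columns)
    de_ids = sorted(de_table.index[de_table["direction"].isin((UP, DOWN))])
    if not de_ids:
        raise ValueError("no UP/DOWN rows in the DE table: nothing to plot")
    ck_name = spec.control_libs[0] if len(spec.control_libs) == 1 else "CK_mean"
    sub = tpm.loc[de_ids]
    ck = sub[spec.control_libs].mean(axis=1).where(lambda s: s > 0, pseudo_tpm)
    values = pd.DataFrame(index=de_ids)
    values[ck_name] = 0.0
    for lib in spec.treatment_libs:
        line = sub[lib].where(sub[lib] > 0, pseudo_tpm)
        values[lib] = np.log2(line / ck)
    values.index.name = "mirna_id"
    return HeatmapMatrix(values=values, ck_column=ck_name)


def cluster_rows(
    matrix: HeatmapMatrix | pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
) -> RowClustering:
    """Agglomerative clustering of heatmap rows; deterministic leaf order."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    values = matrix.values if isinstance(matrix, HeatmapMatrix) else matrix
    if len(values) == 0:
        raise ValueError("cannot cluster an empty matrix")
    names = [str(i) for i in values.index]
    if len(values) == 1:
        return RowClustering(order=[0], newick=f"{names[0]};",
                             linkage_matrix=None)
    data = values.to_numpy(dtype=float)
    if metric == "correlation":
        constant = np.isclose(data.std(axis=1), 0.0)
        if constant.any():
            rows = [names[i] for i in np.flatnonzero(constant)]
            raise ValueError(
                f"correlation distance undefined for constant rows: {rows}"
            )
    z = hierarchy.linkage(pdist(data, metric=metric), method=linkage)
    order = hierarchy.leaves_list(z).tolist()
    newick = _to_newick(z, names)
    return RowClustering(order=order, newick=newick, linkage_matrix=z)


def _to_newick(z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        branch = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{branch:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{branch:.6g}"

    return render(tree, tree.dist) + ";"


def render_report(
    outdir: str | Path,
    matrix: HeatmapMatrix,
    clustering: RowClustering,
    de_table: pd.DataFrame,
    cleaning_stats: Mapping[str, CleaningStats] | None = None,
    length_distributions: Mapping[str, Mapping[int, float]] | None = None,
    heatmap_png: bool = False,
) -> dict[str, Path]:
    """Write the ordered heatmap, dendrogram, DE table and per-library
    summaries as TSV/Newick text (plus an optional raster heatmap)."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc
    ordered = matrix.values.iloc[clustering.order]
    paths: dict[str, Path] = {}

    paths["heatmap"] = outdir / "heatmap.tsv"
    ordered.to_csv(paths["heatmap"], sep="\t", index_label="mirna_id",
                   float_format="%.6g")
    paths["dendrogram"] = outdir / "dendrogram.nwk"
    paths["dendrogram"].write_text(clustering.newick + "\n")
    paths["de_table"] = outdir / "de_table.tsv"
    write_de_table(de_table.sort_index(), paths["de_table"])
    if cleaning_stats is not None:
        rows = []
        for lib in sorted(cleaning_stats):
            stats = cleaning_stats[lib]
            row = {"library": lib, "input": stats.input_count,
                   "clean": stats.clean_count}
            row.update(stats.removed_per_step)
            rows.append(row)
        paths["cleaning_stats"] = outdir / "cleaning_stats.tsv"
        pd.DataFrame(rows).to_csv(paths["cleaning_stats"], sep="\t", index=False)
    if length_distributions is not None:
        paths["length_distribution"] = write_length_distribution(
            {lib: length_distributions[lib] for lib in sorted(length_distributions)},
            outdir / "length_distribution.tsv",
        )
    if heatmap_png:
        paths["heatmap_png"] = _render_png(ordered, outdir / "heatmap.png")
    return paths


def _render_png(ordered: pd.DataFrame, path: Path) -> Path:
    # red = up, green = down, black = no change; symmetric scale around 0
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("rg", ["green", "black", "red"])
    limit = max(float(np.abs(ordered.to_numpy()).max()), 1e-6)
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * ordered.shape[1], 1 + 0.25 * ordered.shape[0])
    )
    im = ax.imshow(ordered.to_numpy(), cmap=cmap, vmin=-limit, vmax=limit,
                   aspect="auto")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2(TPM line / TPM CK)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
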
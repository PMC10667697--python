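"""Figure exports: paired correlation triangles and clustered heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import seaborn as sns

from .cluster import ClusterResult
from .covcorr import CorrelationMatrices


def plot_correlation_triangles(
    cm: CorrelationMatrices, path: str | Path, title: str = ""
) -> Path:
    """Heatmap with phenotypic r below and genotypic r above the diagonal.

    Genotypic entries are clamped to [−1, 1] for the colour scale only.
    """
    tri = cm.paired_triangle().copy()
    tri.values[:] = tri.clip(-1.0, 1.0)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(tri), 0.8 + 0.6 * len(tri)))
    sns.heatmap(
        tri, vmin=-1, vmax=1, cmap="RdBu_r", annot=True, fmt=".2f",
        square=True, cbar_kws={"label": "correlation"}, ax=ax,
    )
    ax.set_title(title or "phenotypic (lower) / genotypic (upper)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_cluster_heatmap(
    result: ClusterResult, path: str | Path, title: str = ""
) -> Path:
    """Two-way clustered heatmap of standardized accession trait profiles."""
    from scipy.cluster.hierarchy import leaves_list

    data = result.scaled
    row_order = leaves_list(result.accession_linkage)
    col_order = leaves_list(result.trait_linkage)
    cg = sns.clustermap(
        data.iloc[row_order, col_order],
        row_cluster=False, col_cluster=False,
        cmap="vlag", center=0,
        figsize=(6, max(4, 0.08 * len(data))),
        yticklabels=len(data) <= 40,
    )
    if title:
        cg.fig.suptitle(title)
    path = Path(path)
    cg.savefig(path, dpi=150)
    plt.close(cg.fig)
    return path
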
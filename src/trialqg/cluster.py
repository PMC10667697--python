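"""Two-way hierarchical clustering of accession trait profiles.

Accessions (and, for the heatmap, traits) are clustered with Ward's
minimum-variance criterion applied to Manhattan distances using the
squared-dissimilarity Lance–Williams update — the convention known as
``ward.D2`` in the R hclust family.  Trait columns are z-scored before
distances are taken, since the panel mixes units (g/plot, µmol m⁻² s⁻¹,
ratios); without standardisation the yield traits would dominate every
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import DesignError


@dataclass
class ClusterResult:
    """Linkage trees, group labels and per-group trait means."""

    accession_linkage: np.ndarray
    trait_linkage: np.ndarray
    groups: pd.Series            # accession -> group label ("I", "II", ...)
    group_means: pd.DataFrame    # group x trait means (original units)
    scaled: pd.DataFrame         # the standardized matrix that was clustered

    @property
    def n_groups(self) -> int:
        return self.groups.nunique()

    def accession_order(self) -> list:
        return list(self.scaled.index[leaves_list(self.accession_linkage)])


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def ward_d2_linkage(X: np.ndarray, metric: str = "cityblock") -> np.ndarray:
    """ward.D2 agglomeration on a precomputed condensed distance matrix.

    scipy's ``linkage(..., method="ward")`` on a condensed matrix applies
    the Lance–Williams recurrence to squared dissimilarities and reports
    square-rooted heights, which is exactly the ward.D2 convention.
    """
    d = pdist(np.asarray(X, float), metric=metric)
    return linkage(d, method="ward")


def cluster_accessions(
    means: pd.DataFrame,
    n_groups: int = 3,
    scale: str = "zscore",
    metric: str = "cityblock",
) -> ClusterResult:
    """Cluster a genotype × trait mean matrix into trait-profile groups.

    Groups are labelled in descending order of their mean standardized
    trait profile, so group I always holds the accessions with the
    highest overall values.

    Parameters
    ----------
    means :
        Genotype × trait matrix with no missing cells.
    n_groups :
        Number of groups to cut the accession tree into.
    scale :
        ``"zscore"`` (per-trait standardisation, default) or ``"none"``.
    """
    means = pd.DataFrame(means)
    if means.isna().any().any():
        raise DesignError("missing cells in the mean matrix; imputation refused")
    if len(means) < n_groups:
        raise DesignError(f"{len(means)} accessions cannot form {n_groups} groups")
    if scale == "zscore":
        sd = means.std(axis=0, ddof=1).replace(0.0, 1.0)
        scaled = (means - means.mean(axis=0)) / sd
    elif scale == "none":
        scaled = means.astype(float)
    else:
        raise ValueError(f"unknown scale policy {scale!r}")

    acc_link = ward_d2_linkage(scaled.to_numpy(), metric=metric)
    trait_link = ward_d2_linkage(scaled.to_numpy().T, metric=metric)
    raw = fcluster(acc_link, t=n_groups, criterion="maxclust")

    # order groups by descending mean standardized profile
    profile = scaled.mean(axis=1)
    order = (
        pd.Series(profile.to_numpy(), index=raw)
        .groupby(level=0)
        .mean()
        .sort_values(ascending=False)
        .index
    )
    relabel = {old: _ROMAN[i] for i, old in enumerate(order)}
    groups = pd.Series([relabel[c] for c in raw], index=means.index, name="group")
    group_means = means.groupby(groups).mean()
    return ClusterResult(
        accession_linkage=acc_link,
        trait_linkage=trait_link,
        groups=groups,
        group_means=group_means,
        scaled=scaled,
    )
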
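"""Hub-gene selection, expression-profile grouping, and hub × module cross-tabulation.

Hubs are the top-k most-connected genes of the network (the study convention
is k = 1200, about 5% of the predicted proteome). Hub expression profiles
are grouped by agglomerative clustering on Euclidean distance (average
linkage), mirroring how stage-specific hub classes — conjugation-early,
conjugation-late, growth-specific, etc. — are read off a clustered heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .mcl import ModulePartition

__all__ = ["HubSet", "select_hubs", "cluster_hub_profiles", "hubs_by_module"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubSet:
    """Degree-ranked hub genes, optionally with expression-profile groups.

    ``ranked`` holds (gene, degree) in descending degree order, boundary
    ties broken by lexicographic gene id; ``min_degree`` is the degree at
    rank k. ``group_of`` is empty until :func:`cluster_hub_profiles` fills
    it with group ids 1…G (numbered by descending group size).
    """

    ranked: tuple[tuple[str, int], ...]
    min_degree: int
    group_of: dict = field(default_factory=dict)

    def __post_init__(self):
        degs = [d for _, d in self.ranked]
        if any(a < b for a, b in zip(degs, degs[1:])):
            raise ValidationError("hub degrees must be non-increasing")
        if degs and min(degs) < self.min_degree:
            raise ValidationError("a hub has degree below min_degree")

    @property
    def k(self) -> int:
        return len(self.ranked)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.ranked)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g for g, _ in self.ranked],
                "degree": [d for _, d in self.ranked],
                "group": [self.group_of.get(g) for g, _ in self.ranked],
            }
        )


def select_hubs(degrees: dict, k: int) -> HubSet:
    """Top-k genes by degree; ties at the boundary broken by lexicographic id.

    If ``k`` exceeds the node count, all nodes are returned with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not degrees:
        raise ValidationError("degree table is empty")
    if k > len(degrees):
        log.warning(
            "requested %d hubs from %d nodes: returning all nodes", k, len(degrees)
        )
        k = len(degrees)
    ordered = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    ranked = tuple((g, int(d)) for g, d in ordered[:k])
    return HubSet(ranked, min_degree=ranked[-1][1])


def cluster_hub_profiles(hubs: HubSet, m: pd.DataFrame, n_groups: int = 6) -> HubSet:
    """Group hub expression profiles by Euclidean-distance agglomerative clustering.

    Average linkage (UPGMA) on the Euclidean distances between hub rows of
    ``m``; the tree is cut into ``n_groups`` flat clusters, and group ids
    are reassigned by descending group size (ties by smallest original
    label) for reproducible naming. Deterministic.
    """
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    if n_groups > hubs.k:
        raise ValidationError(f"n_groups ({n_groups}) exceeds hub count ({hubs.k})")
    missing = [g for g in hubs.genes if g not in m.index]
    if missing:
        raise ValidationError(
            f"hubs absent from the expression matrix: {missing[:5]}"
        )
    x = m.loc[list(hubs.genes)].to_numpy(dtype=float)
    if n_groups == 1 or hubs.k == 1:
        labels = np.ones(hubs.k, dtype=int)
    else:
        z = linkage(pdist(x, metric="euclidean"), method="average")
        labels = fcluster(z, t=n_groups, criterion="maxclust")
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[int(lab)] = sizes.get(int(lab), 0) + 1
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    rename = {lab: i for i, lab in enumerate(order, start=1)}
    group_of = {g: rename[int(lab)] for g, lab in zip(hubs.genes, labels)}
    return replace(hubs, group_of=group_of)


def hubs_by_module(hubs: HubSet, partition: ModulePartition) -> pd.DataFrame:
    """Cross-tabulate hub groups (rows) against modules (columns).

    Hubs absent from the partition are counted under an ``unassigned``
    column; row sums equal the group sizes. Hubs without a group (profiles
    not yet clustered) fall under group 0.
    """
    records = []
    for g, _ in hubs.ranked:
        records.append(
            {
                "group": hubs.group_of.get(g, 0),
                "module": partition.module_of.get(g, "unassigned"),
            }
        )
    df = pd.DataFrame(records)
    tab = pd.crosstab(df["group"], df["module"])
    module_order = [name for name, _ in partition.modules if name in tab.columns]
    if "unassigned" in tab.columns:
        module_order.append("unassigned")
    return tab[module_order]
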
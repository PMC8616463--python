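"""UPGMA clustering of temporal profiles, trend labels, cross-region overlap.

Gene trajectories (Z-scored log expression across developmental ages) are
clustered agglomeratively with average linkage (UPGMA: inter-cluster distance
is the mean over all inter-item pairwise distances) and the tree is cut to a
requested number of flat clusters.  Each cluster's mean profile is regressed
against age in days; the slope sign, outside a small dead-band, labels the
cluster *down*, *up* or *other*.  Down/up gene lists from several brain
regions are then intersected Venn-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from epichron.expression import ExpressionMatrix

#: dead-band on the mean-profile OLS slope (Z-units per day) inside which a
#: cluster is labeled "other" rather than down/up
DEFAULT_TREND_TAU = 0.01

METRICS = ("euclidean", "correlation")


@dataclass
class ClusterAssignment:
    """Flat clustering of one region's gene trajectories."""

    region: str
    k: int
    membership: dict[str, int]                    # gene_id -> 1..k
    mean_profile: dict[int, np.ndarray]           # cluster_id -> per-age mean Z
    ages: list[str]
    trend: dict[int, str] = field(default_factory=dict)  # cluster_id -> label
    linkage_matrix: np.ndarray | None = None
    gene_order: list[str] = field(default_factory=list)

    def genes_in(self, cluster_id: int) -> set[str]:
        return {g for g, c in self.membership.items() if c == cluster_id}

    def genes_with_trend(self, label: str) -> set[str]:
        if not self.trend:
            raise ValueError("clusters are not trend-labeled yet")
        return {
            g for g, c in self.membership.items() if self.trend.get(c) == label
        }

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.membership.values():
            out[c] = out.get(c, 0) + 1
        return out


@dataclass
class OverlapSummary:
    """Venn-style overlap of one trend's gene lists across regions."""

    regions: list[str]
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    intersection_all: int
    union: int
    shared_fraction: float
    shared_genes: set[str] = field(default_factory=set)


def upgma_cluster(
    zmatrix: ExpressionMatrix,
    k: int,
    metric: str = "euclidean",
    cut_height: float | None = None,
) -> ClusterAssignment:
    """UPGMA (average-linkage) clustering of Z-scored gene profiles.

    Parameters
    ----------
    zmatrix
        Z-scored expression matrix for a single region (one column per age).
    k
        Number of flat clusters to cut the dendrogram into (ignored when
        ``cut_height`` is given).
    metric
        Pairwise distance: ``euclidean`` (default) or ``correlation``.
    cut_height
        Optional dendrogram cut height; overrides ``k``.
    """
    if zmatrix.transform_state != "zscore":
        raise ValueError("clustering expects a Z-scored matrix")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    df = zmatrix.values
    n = len(df)
    if cut_height is None and (k < 2 or k > n):
        raise ValueError(f"k={k} out of range for {n} genes")
    regions = {c[0] for c in df.columns}
    if len(regions) != 1:
        raise ValueError(f"expected single-region matrix, got regions {sorted(regions)}")
    (region,) = regions
    ages = [c[1] for c in df.columns]

    Z = linkage(pdist(df.to_numpy(), metric=metric), method="average")
    if cut_height is not None:
        flat = fcluster(Z, t=cut_height, criterion="distance")
    else:
        flat = fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters 1..k by first gene appearance for stable ids
    order: dict[int, int] = {}
    for lab in flat:
        if lab not in order:
            order[lab] = len(order) + 1
    membership = {g: order[lab] for g, lab in zip(df.index, flat)}
    mean_profile = {
        cid: df.loc[[g for g, c in membership.items() if c == cid]].mean(axis=0).to_numpy()
        for cid in sorted(set(membership.values()))
    }
    return ClusterAssignment(
        region=region,
        k=len(mean_profile),
        membership=membership,
        mean_profile=mean_profile,
        ages=ages,
        linkage_matrix=Z,
        gene_order=list(df.index),
    )


def label_trend(
    assignment: ClusterAssignment,
    ages_in_days: Sequence[float],
    tau: float = DEFAULT_TREND_TAU,
) -> ClusterAssignment:
    """Label each cluster down/up/other from its mean-profile OLS slope.

    The cluster's mean Z profile is regressed against age in days; slope
    < -tau labels it *down*, > +tau *up*, otherwise *other*.
    """
    days = np.asarray(ages_in_days, dtype=float)
    if len(days) != len(assignment.ages):
        raise ValueError("ages_in_days length does not match profile length")
    for cid, profile in assignment.mean_profile.items():
        slope = np.polyfit(days, profile, 1)[0]
        if slope < -tau:
            assignment.trend[cid] = "down"
        elif slope > tau:
            assignment.trend[cid] = "up"
        else:
            assignment.trend[cid] = "other"
    return assignment


def overlap_analysis(
    assignments: Mapping[str, ClusterAssignment] | Sequence[ClusterAssignment],
    trend_of_interest: str,
) -> OverlapSummary:
    """Exact Venn overlap of one trend's gene lists across >=2 regions.

    The per-region list is the union of genes in clusters carrying the
    requested trend.  A region with no such cluster is an error naming it.
    """
    if trend_of_interest not in ("down", "up"):
        raise ValueError("trend_of_interest must be 'down' or 'up'")
    if not isinstance(assignments, Mapping):
        assignments = {a.region: a for a in assignments}
    if len(assignments) < 2:
        raise ValueError("overlap analysis needs at least two regions")
    lists: dict[str, set[str]] = {}
    for region, a in assignments.items():
        genes = a.genes_with_trend(trend_of_interest)
        if not genes:
            raise ValueError(
                f"region {region!r} has no cluster with trend {trend_of_interest!r}"
            )
        lists[region] = genes
    regions = list(lists)
    union: set[str] = set().union(*lists.values())
    inter_all = set.intersection(*lists.values())
    pairwise = {
        (r1, r2): len(lists[r1] & lists[r2]) for r1, r2 in combinations(regions, 2)
    }
    return OverlapSummary(
        regions=regions,
        sizes={r: len(s) for r, s in lists.items()},
        pairwise=pairwise,
        intersection_all=len(inter_all),
        union=len(union),
        shared_fraction=len(inter_all) / len(union) if union else 0.0,
        shared_genes=inter_all,
    )


def write_membership(assignment: ClusterAssignment, path: str | Path) -> None:
    """Write (gene_id, region, cluster_id, trend) rows as TSV."""
    rows = [
        (g, assignment.region, c, assignment.trend.get(c, ""))
        for g, c in sorted(assignment.membership.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "region", "cluster_id", "trend"]).to_csv(
        path, sep="\t", index=False
    )


def to_newick(assignment: ClusterAssignment) -> str:
    """Export the dendrogram in Newick format with merge-height branch lengths."""
    if assignment.linkage_matrix is None:
        raise ValueError("assignment carries no linkage matrix")
    tree = to_tree(assignment.linkage_matrix)
    labels = assignment.gene_order

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
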
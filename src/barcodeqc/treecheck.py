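"""Tree- and cluster-based taxonomic consistency flags.

A neighbor-joining tree built from the K2P distance matrix and a
single-linkage clustering at the identification threshold are combined
into per-species inconsistency flags:

``tci``
    individuals of a species that does not form a monophylum on the
    unrooted NJ tree (the species' full count, else 0);
``cl_het``
    individuals sitting in heterogeneous (multi-species) distance
    clusters;
``sp_split``
    individuals of a species scattered over more than one cluster where
    at least one of those clusters is heterogeneous or the species is
    non-monophyletic;
``other_homog``
    individuals of a monophyletic species whose members occupy two or
    more clusters that are all homogeneous (deep intraspecific
    structure, e.g. geographic lineages, rather than label error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from skbio import TreeNode

from barcodeqc.distance import DistanceMatrix


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard rate-corrected agglomeration: at each step the pair
    minimising Q(i,j) = (n-2) d(i,j) - r(i) - r(j) is joined, with ties
    broken by the smallest (row, column) index pair, making the output
    deterministic.  Negative branch lengths are clamped to zero with
    the deficit moved to the sister edge, preserving path lengths.
    Missing distances are imputed at the matrix maximum (they carry no
    signal beyond "far"); the tree is returned rooted at the final
    three-way join, i.e. an unrooted binary topology.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 records")
    d = dm.values.copy()
    if np.isnan(d).any():
        d[np.isnan(d)] = np.nanmax(d)
    nodes: list[TreeNode] = [TreeNode(name=rid) for rid in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimal entry in row-major order = smallest (i, j) pair
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point formulas
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def monophyly_flags(tree: TreeNode, labels: dict[str, str]) -> pd.Series:
    """Per-species ``tci`` counts from unrooted-tree bipartitions.

    A species with >= 2 records is monophyletic iff some edge of the
    unrooted tree induces a bipartition separating exactly its records
    from all others; monotypic samples are trivially monophyletic.
    Non-monophyletic species contribute their full record count.
    """
    tips = frozenset(t.name for t in tree.tips())
    missing = set(labels) - tips
    if missing:
        raise ValueError(f"records absent from tree: {sorted(missing)[:5]}")
    biparts: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips(include_self=True))
        biparts.add(side)
        biparts.add(tips - side)

    by_species: dict[str, set[str]] = {}
    for rid, sp in labels.items():
        by_species.setdefault(sp, set()).add(rid)
    out = {}
    for sp, members in by_species.items():
        if len(members) == 1 or frozenset(members) in biparts:
            out[sp] = 0
        else:
            out[sp] = len(members)
    return pd.Series(out, name="tci").sort_index()


def threshold_clusters(
    dm: DistanceMatrix, threshold: float, linkage_method: str = "single"
) -> pd.Series:
    """Partition records into distance clusters at the threshold.

    ``single`` (default): connected components of the graph joining
    pairs at distance <= threshold — transitive, so chains merge.
    ``complete``: hierarchical complete-linkage cut at the threshold.
    Missing distances never join a pair.  Returns record_id -> integer
    cluster id.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = len(dm)
    d = dm.values
    if linkage_method == "single":
        adj = np.nan_to_num(d, nan=np.inf) <= threshold
        np.fill_diagonal(adj, False)
        _, comp = connected_components(csr_matrix(adj), directed=False)
    elif linkage_method == "complete":
        filled = d.copy()
        if np.isnan(filled).any():
            filled[np.isnan(filled)] = np.nanmax(filled) * 2 + 1
        z = linkage(squareform(filled, checks=False), method="complete")
        comp = fcluster(z, t=threshold, criterion="distance")
    else:
        raise ValueError(f"unknown linkage {linkage_method!r}")
    return pd.Series(comp, index=dm.ids, name="cluster")


@dataclass
class ConsistencyReport:
    """Per-species inconsistency flags plus global cluster counts."""

    per_species: pd.DataFrame  # species, n, tci, cl_het, sp_split, other_homog
    n_heterospecific_clusters: int
    n_species_split_across_clusters: int
    clusters: pd.Series


def consistency_report(
    tree: TreeNode, clusters: pd.Series, labels: dict[str, str]
) -> ConsistencyReport:
    """Combine tree monophyly and threshold clusters into per-species flags."""
    tree_tips = {t.name for t in tree.tips()}
    if tree_tips != set(clusters.index) or tree_tips != set(labels):
        raise ValueError("tree, clusters and labels must cover the same records")

    tci = monophyly_flags(tree, labels)
    lab = pd.Series(labels)
    cluster_species = lab.groupby(clusters).nunique()
    hetero_clusters = set(cluster_species.index[cluster_species > 1])

    rows = []
    n_split_global = 0
    for sp, members in lab.groupby(lab):
        ids = members.index
        own_clusters = set(clusters[ids])
        multi = len(own_clusters) > 1
        if multi:
            n_split_global += 1
        any_het = bool(own_clusters & hetero_clusters)
        cl_het = int(clusters[ids].isin(hetero_clusters).sum())
        monophyletic = tci[sp] == 0
        sp_split = len(ids) if multi and (any_het or not monophyletic) else 0
        other_homog = len(ids) if multi and not any_het and monophyletic else 0
        rows.append(
            {
                "species": sp,
                "n": len(ids),
                "tci": int(tci[sp]),
                "cl_het": cl_het,
                "sp_split": sp_split,
                "other_homog": other_homog,
            }
        )
    per_species = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    return ConsistencyReport(
        per_species=per_species,
        n_heterospecific_clusters=len(hetero_clusters),
        n_species_split_across_clusters=n_split_global,
        clusters=clusters,
    )
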
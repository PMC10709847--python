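"""Class-hierarchy construction from methylation profiles.

Pipeline: per-subtype mean profiles -> restriction to the most variable
probes -> Pearson-correlation distance -> UPGMA (average linkage) tree ->
silhouette-guided cut into groups, with optional manual overrides.

UPGMA is implemented here rather than delegated so that the merge-height
convention (node height = merge distance / 2) and the deterministic
lexicographic tie-break are explicit; the linkage matrix it produces is
scipy-compatible, and scipy's own average linkage serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "SubtypeProfiles", "TaxonomyTree", "GroupAssignment",
    "subtype_means", "top_variance_probes", "pearson_distance", "upgma",
    "silhouette_scores", "choose_groups", "induced_group_tree",
]


@dataclass
class SubtypeProfiles:
    """Per-subtype mean beta profiles (subtypes x probes)."""

    means: pd.DataFrame

    @property
    def subtype_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.means.columns)


def subtype_means(matrix: pd.DataFrame, manifest: pd.DataFrame) -> SubtypeProfiles:
    """Arithmetic mean beta per probe per clinical subtype."""
    missing = set(manifest["sample_id"]) - set(matrix.columns)
    if missing:
        raise ValueError(f"manifest samples absent from matrix: {sorted(missing)[:5]}")
    sub_of = manifest.set_index("sample_id")["subtype"]
    cols = matrix.columns
    labels = sub_of.reindex(cols)
    if labels.isna().any():
        labels = labels.dropna()
        cols = labels.index
    counts = labels.value_counts()
    if (counts < 1).any():
        raise ValueError("empty subtype in manifest")
    means = matrix[cols].T.groupby(labels.to_numpy()).mean()
    means.index.name = "subtype"
    return SubtypeProfiles(means=means)


def top_variance_probes(matrix: pd.DataFrame, fraction: float = 0.01) -> list[str]:
    """The ceil(fraction * n_probes) probes with largest across-sample variance.

    Ties (and the ranking generally) are broken by probe id for
    determinism.  Constant probes sort last, so they are never selected
    while any non-constant probe remains.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank probe variance")
    n_keep = math.ceil(fraction * matrix.shape[0])
    var = matrix.var(axis=1, ddof=1)
    order = var.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n_keep])


def pearson_distance(profiles: SubtypeProfiles) -> pd.DataFrame:
    """Pairwise distance d = 1 - Pearson r between subtype profiles."""
    means = profiles.means
    if means.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    stds = means.std(axis=1, ddof=0)
    constant = stds[stds == 0]
    if len(constant):
        raise ValueError(
            f"constant profile(s), correlation undefined: {list(constant.index)[:5]}"
        )
    r = np.corrcoef(means.to_numpy())
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=means.index, columns=means.index)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTree:
    """Rooted ultrametric tree over subtype leaves.

    ``linkage`` is a scipy-format (n-1) x 4 matrix whose third column is
    the merge *distance*; the node height in the tree convention used
    here is that distance divided by two, so that the two merged children
    sit at equal depth below the node (ultrametricity).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cut(self, k: int) -> pd.Series:
        """Cluster membership (0..k-1) from cutting into k clades."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        flat = cut_tree(self.linkage, n_clusters=k).ravel()
        return pd.Series(flat, index=self.labels)

    def cophenetic(self) -> pd.DataFrame:
        dense = squareform(cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Newick with branch lengths derived from node heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for step, row in enumerate(self.linkage):
            height[n + step] = row[2] / 2.0

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            row = self.linkage[node - n]
            parts = []
            for child in (int(row[0]), int(row[1])):
                bl = height[node] - height[child]
                parts.append(f"{render(child)}:{bl:.10g}")
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def upgma(distances: pd.DataFrame) -> TaxonomyTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the pair of clusters with minimal average distance is
    merged; the merged cluster's distance to any other is the size-weighted
    arithmetic mean of its members' distances.  Ties at the minimal
    distance are broken by the lexicographically smallest pair of cluster
    keys (a cluster's key is the smallest member label), for determinism.
    """
    labels = list(distances.index)
    d0 = distances.to_numpy(dtype=float)
    if np.isnan(d0).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(d0, d0.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")

    # active cluster id -> (key label, size); distances kept in a dict
    key = {i: labels[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {(i, j): d0[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    linkage = np.zeros((n - 1, 4))

    for step in range(n - 1):
        best = None
        for i, j in dist:
            d = dist[(i, j)]
            pair_key = tuple(sorted((key[i], key[j])))
            cand = (d, pair_key, (i, j))
            if best is None or (d < best[0]) or (d == best[0] and pair_key < best[1]):
                best = cand
        d_min, _, (a, b) = best
        new = n + step
        linkage[step] = [a, b, d_min, size[a] + size[b]]
        for other in active - {a, b}:
            da = dist[tuple(sorted((a, other)))]
            db = dist[tuple(sorted((b, other)))]
            dist[(other, new) if other < new else (new, other)] = (
                (size[a] * da + size[b] * db) / (size[a] + size[b])
            )
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        active -= {a, b}
        active.add(new)
        key[new] = min(key[a], key[b])
        size[new] = size[a] + size[b]

    return TaxonomyTree(linkage=linkage, labels=labels)


# ---------------------------------------------------------------------------
# silhouette and group choice
# ---------------------------------------------------------------------------

def silhouette_scores(distances: pd.DataFrame, assignment) -> tuple[pd.Series, float]:
    """Per-point and mean silhouette for a clustering, from a distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance and b the smallest mean distance to another cluster.  Points
    in singleton clusters score 0.
    """
    if isinstance(assignment, Mapping):
        labels = np.array([assignment[x] for x in distances.index])
    else:
        labels = np.asarray(assignment)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if len(uniq) == len(labels):
        s = np.zeros(len(labels))  # all singletons: s = 0 by convention
    else:
        s = silhouette_samples(distances.to_numpy(), labels, metric="precomputed")
    per_point = pd.Series(s, index=distances.index)
    return per_point, float(per_point.mean())


@dataclass
class GroupAssignment:
    """Mapping of subtypes (and derived class labels) to taxonomy groups.

    A cancer type whose subtypes land in different groups is split: its
    class labels become the subtype labels themselves, one class per
    subtype (so every class label routes to exactly one group).
    """

    group_of_subtype: dict[str, str]
    class_of_subtype: dict[str, str]
    group_of_class: dict[str, str]
    n_groups: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    split_types: list[str] = field(default_factory=list)

    @property
    def group_of_type(self) -> dict[str, str]:
        return dict(self.group_of_class)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of_subtype.values()))

    def classes_in_group(self, group: str) -> list[str]:
        return sorted(c for c, g in self.group_of_class.items() if g == group)

    @property
    def multi_type_groups(self) -> list[str]:
        return [g for g in self.groups if len(self.classes_in_group(g)) > 1]

    @property
    def singleton_groups(self) -> list[str]:
        return [g for g in self.groups if len(self.classes_in_group(g)) == 1]

    def class_labels_for(self, manifest: pd.DataFrame) -> pd.Series:
        labels = manifest["subtype"].map(self.class_of_subtype)
        if labels.isna().any():
            bad = manifest.loc[labels.isna(), "subtype"].unique()[:5]
            raise ValueError(f"subtypes without class assignment: {list(bad)}")
        return pd.Series(labels.to_numpy(), index=manifest["sample_id"].to_numpy())

    def group_labels_for(self, manifest: pd.DataFrame) -> pd.Series:
        classes = self.class_labels_for(manifest)
        return classes.map(self.group_of_class)


def choose_groups(
    tree: TaxonomyTree,
    distances: pd.DataFrame,
    type_of_subtype: Mapping[str, str],
    k_range: Sequence[int] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> GroupAssignment:
    """Cut the taxonomy tree into groups guided by the mean silhouette.

    For each candidate k the tree is cut into k clades and the mean
    silhouette computed on the clustering distance matrix; the argmax k
    wins (ties to the smaller k).  ``overrides`` (subtype -> group label,
    applied after the cut) expose the judgment calls that a silhouette
    score alone cannot make — forced merges or splits.
    """
    n = tree.n_leaves
    if k_range is None:
        k_range = range(2, min(20, n - 1) + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > n for k in k_range):
        raise ValueError("k_range must lie within [1, n_leaves]")

    sil_by_k: dict[int, float] = {}
    best_k = None
    for k in k_range:
        if k < 2:
            continue
        flat = tree.cut(k)
        _, mean_s = silhouette_scores(distances.loc[tree.labels, tree.labels], flat)
        sil_by_k[k] = mean_s
        if best_k is None or mean_s > sil_by_k[best_k]:
            best_k = k
    if best_k is None:
        best_k = k_range[0]

    flat = tree.cut(best_k)
    # group ids ordered by first appearance over the leaf label order
    seen: dict[int, str] = {}
    for leaf in tree.labels:
        c = int(flat[leaf])
        if c not in seen:
            seen[c] = f"grp{len(seen) + 1:02d}"
    group_of_subtype = {leaf: seen[int(flat[leaf])] for leaf in tree.labels}

    if overrides:
        for subtype, group in overrides.items():
            if subtype not in group_of_subtype:
                raise ValueError(f"override references unknown subtype {subtype!r}")
            group_of_subtype[subtype] = str(group)

    # derive class labels: split a type whose subtypes straddle groups
    subs_of_type: dict[str, list[str]] = {}
    for s in tree.labels:
        subs_of_type.setdefault(type_of_subtype[s], []).append(s)
    class_of_subtype: dict[str, str] = {}
    group_of_class: dict[str, str] = {}
    split_types: list[str] = []
    for ty, subs in sorted(subs_of_type.items()):
        groups_here = {group_of_subtype[s] for s in subs}
        if len(groups_here) == 1:
            for s in subs:
                class_of_subtype[s] = ty
            group_of_class[ty] = groups_here.pop()
        else:
            split_types.append(ty)
            for s in subs:
                class_of_subtype[s] = s
                group_of_class[s] = group_of_subtype[s]

    return GroupAssignment(
        group_of_subtype=group_of_subtype,
        class_of_subtype=class_of_subtype,
        group_of_class=group_of_class,
        n_groups=len(set(group_of_subtype.values())),
        silhouette_by_k=sil_by_k,
        split_types=split_types,
    )


def induced_group_tree(newick: str, group_of_leaf: Mapping[str, str]) -> tuple[str, bool]:
    """Collapse a subtype-level tree to a group-level topology.

    Checks that every group's leaves form a clade (monophyly); if so,
    prunes to one representative leaf per group and relabels it with the
    group name.  Returns (group-level newick, all_groups_monophyletic).
    When a group is not monophyletic the returned newick still uses one
    representative per group but the flag is False.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    leaves_of_group: dict[str, list[str]] = {}
    for leaf, grp in group_of_leaf.items():
        leaves_of_group.setdefault(grp, []).append(leaf)

    monophyletic = True
    for grp, leaves in leaves_of_group.items():
        taxa = [t for t in tree.taxon_namespace if t.label in set(leaves)]
        if len(taxa) != len(leaves):
            raise ValueError(f"group {grp} references leaves absent from tree")
        if len(taxa) == 1:
            continue
        mrca = tree.mrca(taxa=taxa)
        mrca_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        if mrca_leaves != set(leaves):
            monophyletic = False

    reps = {grp: sorted(leaves)[0] for grp, leaves in leaves_of_group.items()}
    keep = set(reps.values())
    tree.retain_taxa_with_labels(list(keep))
    label_to_group = {rep: grp for grp, rep in reps.items()}
    for taxon in tree.taxon_namespace:
        if taxon.label in label_to_group:
            taxon.label = label_to_group[taxon.label]
    out = tree.as_string(schema="newick", suppress_edge_lengths=True,
                         suppress_rooting=True).strip()
    return out, monophyletic
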
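"""UPGMA lineage delimitation at a maximum intraspecific divergence threshold.

Sequences are clustered by average linkage (UPGMA) on pairwise distances,
giving an ultrametric tree whose node heights are in substitutions/site per
lineage.  Cutting the tree at half the divergence threshold tau yields
lineages (LMDHs): the maximal clades in which every within-clade cophenetic
distance is <= tau, while merging any two of them would exceed tau.

Ties between equally close cluster pairs are broken deterministically by the
lexicographically smallest combined member-label tuple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_distance import DistanceMatrix

__all__ = [
    "TreeNode",
    "UltrametricTree",
    "LineagePartition",
    "upgma",
    "cophenetic",
    "cut_tree",
    "delimit",
    "summarize_partition",
    "percentage",
    "DEFAULT_THRESHOLDS",
]

# Maximum intraspecific divergence thresholds (cophenetic, substitutions/site).
# The spider value is the study default; the beetle value follows the antecedent
# beetle survey and is an assumption, kept configurable.
DEFAULT_THRESHOLDS = {"spider": 0.068, "beetle": 0.05}

ULTRAMETRIC_TOL = 1e-9


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric tree. Leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]


@dataclass
class UltrametricTree:
    """Rooted ultrametric tree; node heights in substitutions/site per lineage."""

    root: TreeNode

    @property
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def validate(self, tol: float = ULTRAMETRIC_TOL) -> None:
        """Check leaf height 0, child < parent height (within tol)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                if abs(node.height) > tol:
                    raise ValueError(f"leaf {node.label!r} not at height 0")
            else:
                for ch in node.children:
                    if ch.height > node.height + tol:
                        raise ValueError("child height exceeds parent height")
                    stack.append(ch)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma(dm: DistanceMatrix, sizes: list[int] | np.ndarray | None = None) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Merge height is half the inter-cluster distance; after a merge the
    distance from the new cluster to any other is the size-weighted mean of
    its members' distances.  Among equal-minimum pairs, the pair whose sorted
    combined label tuple is lexicographically smallest merges first.

    ``sizes`` seeds initial cluster sizes (defaults to 1 each): a label with
    size m behaves exactly like m identical copies pre-merged at height 0,
    which is how exact-duplicate sequences are folded in without inflating
    the matrix.

    A cached row-minimum makes the common path O(n^2).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite entry in distance matrix")

    d = dm.d.astype(np.float64).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    if sizes is None:
        sizes = np.ones(n, dtype=np.int64)
    else:
        sizes = np.asarray(sizes, dtype=np.int64).copy()
        if sizes.shape != (n,) or np.any(sizes < 1):
            raise ValueError("sizes must be positive, one per label")
    nodes: list[TreeNode] = [TreeNode(height=0.0, label=lab) for lab in dm.labels]
    member_labels: list[tuple[str, ...]] = [(lab,) for lab in dm.labels]

    row_min = d.min(axis=1)

    def recompute_row(i: int) -> None:
        row = np.where(active, d[i], np.inf)
        row[i] = np.inf
        row_min[i] = row.min()

    for _ in range(n - 1):
        act_idx = np.flatnonzero(active)
        if len(act_idx) == 1:
            break
        m = row_min[act_idx].min()
        # all pairs attaining the minimum (usually exactly one)
        cand_rows = act_idx[row_min[act_idx] == m]
        candidates: list[tuple[tuple[str, ...], int, int]] = []
        for i in cand_rows:
            js = np.flatnonzero(active & (d[i] == m))
            for j in js:
                if j > i:
                    key = tuple(sorted(member_labels[i] + member_labels[int(j)]))
                    candidates.append((key, int(i), int(j)))
        key, a, b = min(candidates)
        height = m / 2.0

        new_node = TreeNode(height=height, children=(nodes[a], nodes[b]))
        # merge b into a
        wa, wb = sizes[a], sizes[b]
        new_row = (wa * d[a] + wb * d[b]) / (wa + wb)
        d[a, :] = new_row
        d[:, a] = new_row
        d[a, a] = np.inf
        d[b, :] = np.inf
        d[:, b] = np.inf
        active[b] = False
        sizes[a] = wa + wb
        nodes[a] = new_node
        member_labels[a] = key
        row_min[b] = np.inf
        recompute_row(a)
        # rows whose cached minimum involved a or b must be refreshed; others
        # only need comparing against the new distance to cluster a
        for k in np.flatnonzero(active):
            if k == a:
                continue
            if d[k, a] <= row_min[k]:
                row_min[k] = d[k, a]
            else:
                recompute_row(int(k))

    root_idx = int(np.flatnonzero(active)[0])
    return UltrametricTree(root=nodes[root_idx])


def cophenetic(tree: UltrametricTree) -> DistanceMatrix:
    """Cophenetic distances: d(i, j) = 2 x height of the MRCA of i and j."""
    labels = tree.leaf_labels
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def visit(node: TreeNode) -> list[int]:
        if node.is_leaf:
            return [index[node.label]]
        groups = [visit(ch) for ch in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        d[i, j] = d[j, i] = 2.0 * node.height
        return [i for g in groups for i in g]

    visit(tree.root)
    sites = np.zeros((n, n), dtype=np.int64)
    return DistanceMatrix(labels=labels, d=d, sites=sites, model="COPHENETIC")


@dataclass
class LineagePartition:
    """Assignment of specimens to LMDHs at a divergence threshold tau."""

    threshold: float
    assignment: dict[str, str]                      # specimen_id -> lmdh_id
    lineages: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lineages:
            groups: dict[str, list[str]] = {}
            for sid, lid in self.assignment.items():
                groups.setdefault(lid, []).append(sid)
            self.lineages = groups

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def labels_for(self, ids: list[str]) -> list[str]:
        return [self.assignment[i] for i in ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"specimen_id": list(self.assignment), "lmdh_id": list(self.assignment.values())}
        )


def cut_tree(tree: UltrametricTree, threshold: float, prefix: str = "LMDH") -> LineagePartition:
    """Cut an ultrametric tree at divergence threshold ``tau``.

    Lineages are the maximal subtrees whose merge heights are all <= tau/2,
    i.e. every within-lineage cophenetic distance is <= tau and each
    lineage's parent merge exceeds tau/2.  Lineage ids are assigned in order
    of each lineage's smallest member label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    half = threshold / 2.0
    clusters: list[list[str]] = []

    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf or node.height <= half:
            clusters.append(node.leaf_labels())
        else:
            stack.extend(node.children)

    clusters.sort(key=lambda ms: min(ms))
    width = max(4, len(str(len(clusters))))
    assignment: dict[str, str] = {}
    lineages: dict[str, list[str]] = {}
    for k, members in enumerate(clusters, start=1):
        lid = f"{prefix}{k:0{width}d}"
        lineages[lid] = sorted(members)
        for m in members:
            assignment[m] = lid
    return LineagePartition(threshold=threshold, assignment=assignment, lineages=lineages)


def delimit(
    seqs, threshold: float, model: str = "K2P", prefix: str = "LMDH"
) -> tuple[LineagePartition, UltrametricTree]:
    """Delimit lineages from an alignment: distances -> UPGMA -> cut at tau.

    Exact-duplicate sequences are collapsed before the distance matrix and
    re-expanded afterwards; duplicate multiplicities seed the UPGMA cluster
    sizes, so heights equal those of the full matrix.  Returns the partition
    over all specimens and the (collapsed) UPGMA tree.
    """
    from .seq_distance import distance_matrix

    rep_of: dict[str, str] = {}
    reps: list[str] = []
    counts: dict[str, int] = {}
    by_seq: dict[str, str] = {}
    for sid, s in zip(seqs.ids, seqs.sequences):
        if s not in by_seq:
            by_seq[s] = sid
            reps.append(sid)
            counts[sid] = 0
        rep_of[sid] = by_seq[s]
        counts[by_seq[s]] += 1

    if len(reps) == 1:
        lid = f"{prefix}0001"
        assignment = {sid: lid for sid in seqs.ids}
        tree = UltrametricTree(root=TreeNode(height=0.0, label=reps[0]))
        return LineagePartition(threshold=threshold, assignment=assignment), tree

    dm = distance_matrix(seqs.subset(reps), model=model)
    tree = upgma(dm, sizes=[counts[r] for r in reps])
    rep_partition = cut_tree(tree, threshold, prefix=prefix)
    assignment = {sid: rep_partition.assignment[rep_of[sid]] for sid in seqs.ids}
    return LineagePartition(threshold=threshold, assignment=assignment), tree


def percentage(a: int, b: int, decimals: int = 1) -> float:
    """100*a/b rounded half-up to ``decimals`` places (0 -> nearest integer)."""
    if b == 0:
        raise ZeroDivisionError("denominator is zero")
    scale = 10 ** decimals
    return float(np.floor(100.0 * a / b * scale + 0.5) / scale)


def lineage_dispersal(members_meta: pd.DataFrame) -> str:
    """Dispersal category of a lineage: the unanimous member category.

    Mixed categories trigger a warning and map to "unassigned".
    """
    cats = set(members_meta["dispersal"])
    if len(cats) == 1:
        return next(iter(cats))
    warnings.warn(
        f"mixed dispersal categories within lineage: {sorted(cats)}; set to 'unassigned'",
        stacklevel=2,
    )
    return "unassigned"


def summarize_partition(partition: LineagePartition, metadata: pd.DataFrame) -> dict:
    """Counts and percentages per order and island for a lineage partition.

    Returns a dict with ``per_order`` (LMDH count and per-dispersal count and
    percentage, 1 decimal) and ``per_island`` (LMDH counts per order; a
    lineage counts on every island where it was sampled).
    """
    meta = metadata
    if "specimen_id" in meta.columns:
        meta = meta.set_index("specimen_id")
    rows = []
    for lid, members in partition.lineages.items():
        mm = meta.loc[members]
        order = mm["order"].iloc[0]
        rows.append(
            {
                "lmdh_id": lid,
                "order": order,
                "dispersal": lineage_dispersal(mm),
                "islands": sorted(set(mm["island"])),
                "n": len(members),
            }
        )
    ldf = pd.DataFrame(rows)

    per_order: dict[str, dict] = {}
    for order, grp in ldf.groupby("order"):
        total = len(grp)
        cats = {}
        for cat, cgrp in grp.groupby("dispersal"):
            cats[cat] = {"count": len(cgrp), "pct": percentage(len(cgrp), total, 1)}
        per_order[order] = {"n_lmdh": total, "dispersal": cats}

    per_island: dict[str, dict[str, int]] = {}
    for _, row in ldf.iterrows():
        for isl in row["islands"]:
            per_island.setdefault(isl, {})
            per_island[isl][row["order"]] = per_island[isl].get(row["order"], 0) + 1

    return {"per_order": per_order, "per_island": per_island, "lineage_table": ldf}
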
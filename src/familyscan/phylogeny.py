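"""Domain-anchored alignment, p-distances, neighbor-joining and subgroups.

The multiple alignment is induced by the repeat PSSM: each retained repeat
contributes exactly ``width`` columns, proteins missing a repeat slot get a
gap block, so column homology is defined by the profile rather than by a
de novo aligner. Trees are built with the Saitou-Nei neighbor-joining
agglomeration; bootstrap support is the percentage of column-resampled
replicate trees containing each original bipartition. Subgroup labels
propagate from reference (anchor) leaves to queries by patristic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_scan import MybRepeatHit, RepeatPSSM

__all__ = [
    "DomainAlignment",
    "TreeNode",
    "PhyloTree",
    "SubgroupAssignment",
    "build_domain_alignment",
    "p_distance",
    "poisson_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_subgroups",
]

GAP = "-"


@dataclass
class DomainAlignment:
    """Fixed-width alignment of concatenated repeat domains."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "DomainAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return DomainAlignment(ids=list(self.ids), rows=rows)


def build_domain_alignment(hits_by_protein: dict[str, list[MybRepeatHit]],
                           sequences: dict[str, str],
                           pssm: RepeatPSSM) -> DomainAlignment:
    """Concatenate repeat windows into aligned rows, one slot per repeat rank.

    The number of repeat slots is the maximum repeat count over proteins;
    proteins with fewer repeats are padded with gap blocks on the right
    (repeat ranks are left-anchored: a 1R protein's single repeat occupies
    slot 1). Proteins with no retained hit are excluded.
    """
    kept = {pid: sorted(h, key=lambda x: x.start)
            for pid, h in hits_by_protein.items() if h}
    if len(kept) < 2:
        raise ValueError("need at least 2 proteins with repeats")
    max_slots = max(len(h) for h in kept.values())
    ids, rows = [], []
    for pid in kept:
        seq = sequences[pid]
        parts = [seq[h.start - 1 : h.end] for h in kept[pid]]
        parts += [GAP * pssm.width] * (max_slots - len(parts))
        ids.append(pid)
        rows.append("".join(parts))
    return DomainAlignment(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# distances


def p_distance(alignment: DomainAlignment, on_empty: str = "error") -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of gap columns.

    ``on_empty`` controls pairs with zero comparable columns: "error" raises,
    "max" substitutes the saturation value 0.75 (used by bootstrap replicates
    where resampling can drop all shared columns).
    """
    n = len(alignment.ids)
    arr = np.array([list(r) for r in alignment.rows])
    gaps = arr == GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            m = int(ok.sum())
            if m == 0:
                if on_empty == "max":
                    d = 0.75
                else:
                    raise ValueError(
                        f"no comparable columns between {alignment.ids[i]} and {alignment.ids[j]}"
                    )
            else:
                d = float((arr[i, ok] != arr[j, ok]).sum()) / m
            D[i, j] = D[j, i] = d
    return D


def poisson_distance(alignment: DomainAlignment, on_empty: str = "error") -> np.ndarray:
    """Poisson-corrected distance -ln(1 - p); saturated pairs clamp at p=0.95."""
    p = p_distance(alignment, on_empty=on_empty)
    return -np.log(1 - np.minimum(p, 0.95))


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = str(int(round(node.support)))
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set on one side of an edge."""
        all_leaves = frozenset(self.leaf_names)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                # canonical side: the lexicographically smaller frozenset
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: sorted(s)))
            return below

        walk(self.root)
        return splits

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths along branches."""
        leaves: list[str] = []
        index: dict[str, int] = {}

        def collect(node: TreeNode) -> None:
            if node.is_leaf:
                index[node.name] = len(leaves)
                leaves.append(node.name)
            for c in node.children:
                collect(c)

        collect(self.root)
        n = len(leaves)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.name]: 0.0}
            depth_maps = [walk(c) for c in node.children]
            for k, dm in enumerate(depth_maps):
                for key in dm:
                    dm[key] += node.children[k].length
            for a in range(len(depth_maps)):
                for b in range(a + 1, len(depth_maps)):
                    for i, di in depth_maps[a].items():
                        for j, dj in depth_maps[b].items():
                            D[i, j] = D[j, i] = di + dj
            merged: dict[int, float] = {}
            for dm in depth_maps:
                merged.update(dm)
            return merged

        walk(self.root)
        return leaves, D

    def clade_sizes_containing(self, a: str, b: str) -> int:
        """Size of the smallest clade containing both named leaves."""
        best = [len(self.leaf_names)]

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c in node.children:
                below |= walk(c)
            if a in below and b in below:
                best[0] = min(best[0], len(below))
            return below

        walk(self.root)
        return best[0]


def nj_tree(D: np.ndarray, names: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the pair sum preserved
    on the sibling. An all-zero matrix yields a star tree with zero-length
    branches. Two taxa get d/2 each.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(names) or n < 2:
        raise ValueError("distance matrix and names mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    if np.allclose(D, 0):
        root = TreeNode(children=[TreeNode(name=nm, length=0.0) for nm in names])
        return PhyloTree(root)
    if n == 2:
        half = D[0, 1] / 2
        root = TreeNode(children=[TreeNode(name=names[0], length=half),
                                  TreeNode(name=names[1], length=half)])
        return PhyloTree(root)

    nodes = [TreeNode(name=nm) for nm in names]
    active = list(range(n))
    dist = D.copy()

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = np.unravel_index(np.argmin(Q), Q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj = dij
            li = 0.0
        elif lj < 0:
            li = dij
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row)] = new_row
        dist[: len(new_row), -1] = new_row
        dist[-1, -1] = 0.0
        nodes.append(parent)
        k = dist.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    d = max(dist[i, j], 0.0)
    # the final edge of length d is split evenly across the root; patristic
    # distances (the unrooted quantity) are unaffected by the split point
    nodes[i].length = d / 2
    nodes[j].length = d / 2
    root = TreeNode(children=[nodes[i], nodes[j]])
    return PhyloTree(root)


def bootstrap_support(alignment: DomainAlignment, n_reps: int, seed: int,
                      distance: str = "p") -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each original
    bipartition's support is the percentage of replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dfun = p_distance if distance == "p" else poisson_distance
    tree = nj_tree(dfun(alignment), alignment.ids)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = alignment.resample_columns(rng)
        rep_tree = nj_tree(dfun(rep, on_empty="max"), rep.ids)
        rep_splits = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_splits:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaf_names)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            key = min(below, all_leaves - below, key=lambda s: sorted(s))
            node.support = 100.0 * counts[key] / n_reps
        return below

    annotate(tree.root)
    return tree


@dataclass(frozen=True)
class SubgroupAssignment:
    protein_id: str
    subgroup: str
    anchor_id: str


def assign_subgroups(tree: PhyloTree, reference_labels: dict[str, str]) -> list[SubgroupAssignment]:
    """Label each unlabelled leaf with its nearest reference leaf's subgroup.

    Nearest is by patristic distance; exact ties break by the smaller
    enclosing clade (then anchor id), so assignment is deterministic.
    """
    anchors = [l for l in tree.leaf_names if l in reference_labels]
    if not anchors:
        raise ValueError("tree contains no labelled reference leaves")
    leaves, D = tree.patristic_distances()
    idx = {nm: i for i, nm in enumerate(leaves)}
    out = []
    for leaf in tree.leaf_names:
        if leaf in reference_labels:
            continue
        best = min(
            anchors,
            key=lambda a: (
                round(D[idx[leaf], idx[a]], 12),
                tree.clade_sizes_containing(leaf, a),
                a,
            ),
        )
        out.append(SubgroupAssignment(protein_id=leaf,
                                      subgroup=reference_labels[best],
                                      anchor_id=best))
    return out
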
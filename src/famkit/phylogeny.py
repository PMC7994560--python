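"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap
support and anchor-based subfamily assignment.

Neighbor joining follows the Saitou-Nei agglomeration on the Q-criterion
with a deterministic tie-break (the lexicographically smallest id pair), so
runs are reproducible and input-order independent away from ties.  On an
additive distance matrix the method recovers the generating tree exactly.

Subfamily assignment places each query leaf by the smallest edge-induced
bipartition side that contains it together with at least one labelled
reference anchor; queries whose smallest anchored clade mixes labels are
reported as orphans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io import AlignedBlock


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class PhyloConfig:
    n_bootstrap: int = 1000
    support_display_min: float = 50.0
    rng_seed: int = 0
    distance_model: str = "p"  # "p" or "poisson"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.distance_model not in {"p", "poisson"}:
            raise ValueError("distance_model must be 'p' or 'poisson'")


def _encode(aln: AlignedBlock) -> np.ndarray:
    return np.array([list(row) for row in aln.rows], dtype="U1")


def p_distance(aln: AlignedBlock, model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p-distance (optionally Poisson-corrected).

    For each pair, columns where either row has a gap are dropped; the
    distance is mismatches / compared columns.  A pair with no comparable
    columns is an error.
    """
    if aln.n_rows < 3:
        raise ValueError("distance matrix requires at least 3 rows")
    chars = _encode(aln)
    gaps = chars == "-"
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gaps[i] | gaps[j])
            m = int(usable.sum())
            if m == 0:
                raise ValueError(
                    f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "comparable columns"
                )
            p = float((chars[i, usable] != chars[j, usable]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for pair "
                        f"{aln.ids[i]!r}/{aln.ids[j]!r}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(aln.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining, deterministic under ties.

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined; among Q-ties the lexicographically smallest (id_i, id_j) pair
    wins.  Negative branch lengths are clamped to zero.  Returns an
    unrooted dendropy tree (seed node of degree 3).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(list(dm.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)

    # live nodes keyed by a sorted label used only for tie-breaking
    nodes: dict[str, dendropy.Node] = {}
    for tid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(tid))
        nodes[tid] = node
    labels = list(dm.ids)
    d = {a: {b: float(dm.value(a, b)) for b in labels if b != a} for a in labels}

    while len(labels) > 3:
        r = len(labels)
        row_sums = {a: sum(d[a].values()) for a in labels}
        best = None
        for idx, a in enumerate(labels):
            for b in labels[idx + 1 :]:
                q = (r - 2) * d[a][b] - row_sums[a] - row_sums[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d[a][b]
        la = 0.5 * dab + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = dab - la
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = max(la, 0.0)
        nb.edge.length = max(lb, 0.0)
        new_label = min(a, b)
        new_d = {}
        for c in labels:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (d[a][c] + d[b][c] - dab)
            del d[c][a]
            del d[c][b]
        labels = [c for c in labels if c not in (a, b)]
        del d[a], d[b]
        for c in labels:
            d[c][new_label] = new_d[c]
        d[new_label] = new_d
        labels.append(new_label)
        labels.sort()
        nodes[new_label] = parent

    # final star join of the last three lineages
    a, b, c = sorted(labels)
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    root = tree.seed_node
    for label, length in ((a, la), (b, lb), (c, lc)):
        node = nodes[label]
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def _bipartition_keys(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side
    by sorted-label order is canonical via frozenset of both sides)."""
    all_leaves = frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    keys: set[frozenset[str]] = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            keys.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return keys


def bootstrap_support(
    aln: AlignedBlock, cfg: PhyloConfig | None = None
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_bootstrap`` times; each
    replicate is rebuilt with the same distance model and NJ; the support of
    an internal edge is the percentage of replicates containing its
    bipartition.  Supports are stored as internal node labels (and
    ``edge.support``); values below ``support_display_min`` are kept in the
    data but suppressed by :func:`render_support_labels`.
    """
    cfg = cfg or PhyloConfig()
    if aln.n_rows < 4:
        raise ValueError("bootstrap requires at least 4 rows")
    main = nj_tree(p_distance(aln, cfg.distance_model))
    chars = _encode(aln)
    rng = np.random.default_rng(cfg.rng_seed)
    counts: dict[frozenset[str], int] = {}
    ncol = aln.n_columns
    for _ in range(cfg.n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = tuple("".join(r) for r in chars[:, cols])
        rep = AlignedBlock(aln.ids, rep_rows)
        rep_tree = nj_tree(p_distance(rep, cfg.distance_model))
        for key in _bipartition_keys(rep_tree):
            counts[key] = counts.get(key, 0) + 1
    all_leaves = frozenset(aln.ids)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        other = all_leaves - side
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        support = 100.0 * counts.get(key, 0) / cfg.n_bootstrap
        node.label = f"{support:g}"
        node.edge.support = support
    return main


def render_support_labels(tree: dendropy.Tree, display_min: float = 50.0) -> None:
    """Blank internal labels whose support is below the display cutoff."""
    for node in tree.preorder_node_iter():
        support = getattr(node.edge, "support", None)
        if support is not None and support < display_min:
            node.label = None


ORPHAN = "orphan"


def assign_subfamilies(
    tree: dendropy.Tree, anchors: dict[str, str]
) -> dict[str, str]:
    """Assign query leaves to subfamilies via labelled anchor leaves.

    For every non-anchor leaf, consider each edge-induced bipartition side
    containing it that also contains at least one anchor; take the smallest
    such side.  If all its anchors share one label, the query gets that
    label; otherwise it is an orphan.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    anchor_set = set(anchors)
    if not anchor_set & set(leaves):
        raise ValueError("tree contains no anchor leaves")
    missing = anchor_set - set(leaves)
    if missing:
        raise ValueError(f"anchors absent from tree: {sorted(missing)}")
    all_leaves = frozenset(leaves)
    # collect both sides of every edge bipartition
    sides: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sides.append(side)
        sides.append(all_leaves - side)
    assignment: dict[str, str] = {}
    for query in leaves:
        if query in anchor_set:
            continue
        best: frozenset[str] | None = None
        for side in sides:
            if query not in side or not (side & anchor_set):
                continue
            if best is None or len(side) < len(best):
                best = side
        if best is None:
            assignment[query] = ORPHAN
            continue
        labels = {anchors[a] for a in best & anchor_set}
        assignment[query] = labels.pop() if len(labels) == 1 else ORPHAN
    return assignment
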
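"""Distance-based neighbor-joining trees with bootstrap support.

Distances come from pairwise comparison of MSA rows: the default is the
p-distance (1 - fraction identical over columns where neither row is
gapped), optionally Poisson-corrected as -ln(identity fraction) and capped.
Trees are built by canonical neighbor joining (Q-criterion), with ties
broken by the smallest accession pair and negative branch lengths clamped to
zero (the deficit moved to the sibling edge). Bootstrap support for each
internal bipartition of the point-estimate tree is the percentage of
column-resampled replicate trees containing it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msa import MSA

DEFAULT_MAX_DISTANCE = 10.0


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary root node of degree >= 2."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.10g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set of one side (the side not
        containing the lexicographically smallest leaf, a canonical choice)."""
        all_leaves = set(self.root.leaves())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for child in node.children:
                side = set(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    if anchor in side:
                        side = all_leaves - side
                    splits.add(frozenset(side))
                walk(child)
        walk(self.root)
        return splits


def parse_newick(text: str) -> Tree:
    """Parse the subset of Newick this package writes (supports as internal
    node labels, branch lengths on every edge)."""
    tokens = re.findall(r"\(|\)|,|;|[^(),;:]+|:", text.strip())
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while tokens[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            assert tokens[pos] == ")", f"expected ')' at token {pos}"
            pos += 1
            if tokens[pos] not in (":", ",", ")", ";"):
                node.support = float(tokens[pos])
                pos += 1
        else:
            node.name = tokens[pos]
            pos += 1
        if tokens[pos] == ":":
            pos += 1
            node.length = float(tokens[pos])
            pos += 1
        return node

    root = parse_node()
    assert tokens[pos] == ";", "missing trailing semicolon"
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    accessions: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.accessions)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match accession count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("distances must be finite")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")


def distance_matrix(
    msa: MSA,
    model: str = "p",
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """Pairwise distances from MSA rows.

    ``p``: 1 - fraction identical over pairwise non-gap columns.
    ``poisson``: -ln(identity fraction), capped at ``max_distance``
    (pairs with identity <= exp(-max_distance) saturate at the cap).
    Pairs with no shared non-gap column get the maximum distance for the
    model (1 for p, the cap for poisson).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    cm = msa.column_matrix()
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (cm[i] >= 0) & (cm[j] >= 0)
            tot = int(both.sum())
            if tot == 0:
                ident = 0.0
            else:
                ident = float((cm[i][both] == cm[j][both]).sum()) / tot
            if model == "p":
                dij = 1.0 - ident
            else:
                dij = (
                    max_distance
                    if ident <= np.exp(-max_distance)
                    else min(-np.log(ident), max_distance)
                )
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(accessions=list(msa.accessions), matrix=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining.

    At each step the pair minimising Q(i, j) = (n - 2) d(i, j) - r_i - r_j
    is joined (ties by smallest accession pair). Negative branch lengths are
    clamped to zero with the deficit shifted to the sibling edge.
    """
    n = len(dm.accessions)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=acc) for i, acc in enumerate(dm.accessions)
    }
    labels: dict[int, str] = {i: acc for i, acc in enumerate(dm.accessions)}
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dm.matrix[i, j])

    def dist(i: int, j: int) -> float:
        return d[(min(i, j), max(i, j))]

    active = set(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        nodes[next_id] = new
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(next_id, k), max(next_id, k))] = max(dk, 0.0)
        active -= {i, j}
        active.add(next_id)
        next_id += 1

    a, b, c = sorted(active, key=lambda k: labels[k])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root)


def bootstrap(
    msa: MSA,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "p",
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate from one seeded
    stream; the support of each internal bipartition of the point-estimate
    tree is the percentage of replicate trees containing it.
    """
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    point = nj_tree(distance_matrix(msa, model=model, max_distance=max_distance))
    target = point.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = MSA(accessions=list(msa.accessions), rows=rep_rows)
        rep_tree = nj_tree(
            distance_matrix(rep, model=model, max_distance=max_distance)
        )
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str], anchor: str) -> None:
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canonical = (
                        frozenset(all_leaves - side) if anchor in side else side
                    )
                    child.support = 100.0 * counts[canonical] / n_replicates
                annotate(child, all_leaves, anchor)

    leaves = frozenset(point.root.leaves())
    annotate(point.root, leaves, min(leaves))
    return point


def support_table(tree: Tree) -> pd.DataFrame:
    rows = []
    def walk(node: TreeNode) -> None:
        for child in node.children:
            if not child.is_leaf and child.support is not None:
                rows.append(
                    {
                        "clade": ",".join(sorted(child.leaves())),
                        "support": child.support,
                    }
                )
            walk(child)
    walk(tree.root)
    return pd.DataFrame(rows)
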
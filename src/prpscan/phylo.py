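"""Pairwise evolutionary distances and neighbor-joining trees.

Supports the whole-sequence versus bait-region comparison: distances are
computed on a full alignment and on the bait columns alone, and the per-pair
ratio quantifies how much faster the bait evolves than the rest of the
chain.

Models: p-distance (fraction of differing sites among pairwise-complete
columns) and its Poisson multiple-hit correction -ln(1 - p).  Gap treatment
is pairwise deletion, the sensible default when the bait sub-alignment is
only a few dozen columns.  Trees are built with the Saitou-Nei
neighbor-joining algorithm with deterministic tie-breaking; bootstrap
support is the percentage of column-resampled replicate trees containing
each internal bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InfiniteDistanceError",
    "DistanceMatrix",
    "TreeNode",
    "pairwise_distance",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "region_vs_whole_report",
]

MODELS = ("p-distance", "poisson")


class InfiniteDistanceError(ValueError):
    """Poisson correction undefined (p >= 1) for a named taxon pair."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative taxon-by-taxon distance matrix."""

    labels: list[str]
    values: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])


def _pair_distance(a: str, b: str, model: str) -> float:
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return float("nan")
    p = mismatches / compared
    if model == "p-distance":
        return p
    if p >= 1.0:
        raise InfiniteDistanceError("p >= 1: Poisson-corrected distance infinite")
    return -math.log(1.0 - p)


def pairwise_distance(
    labels: list[str], aligned: list[str], model: str = "poisson"
) -> DistanceMatrix:
    """All pairwise distances over an alignment, pairwise gap deletion."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if len(labels) != len(aligned):
        raise ValueError("labels and sequences differ in number")
    lengths = {len(s) for s in aligned}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal length")
    n = len(labels)
    d = np.zeros((n, n))
    seqs = [s.upper() for s in aligned]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = _pair_distance(seqs[i], seqs[j], model)
            except InfiniteDistanceError:
                raise InfiniteDistanceError(
                    f"p >= 1 between {labels[i]!r} and {labels[j]!r}: "
                    "Poisson-corrected distance infinite"
                ) from None
    return DistanceMatrix(labels=list(labels), values=d, model=model)


@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary trifurcating root."""

    name: str | None = None
    length: float = 0.0  # branch to parent
    support: float | None = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.10g}"
        return f"({inner}){label}:{self.length:.10g}"


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaf_names())


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest leaf).
    A negative branch length is clamped to zero and the deficit moved to
    the sibling edge, preserving the sum of the two estimates.  The result
    is returned rooted at the final three-way (or two-way) junction.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    d = {(i, j): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                tie_key = tuple(sorted((_min_leaf(node_of[i]), _min_leaf(node_of[j]))))
                cand = (q, tie_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[node_of[i], node_of[j]])
        node_of[i].length, node_of[j].length = li, lj
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(u, k), max(u, k))] = max(0.0, duk)
        node_of[u] = parent
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
        lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
        lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
        root = TreeNode(children=[node_of[i], node_of[j], node_of[k]])
        node_of[i].length = max(0.0, li)
        node_of[j].length = max(0.0, lj)
        node_of[k].length = max(0.0, lk)
    else:  # pragma: no cover - unreachable for n >= 3
        raise AssertionError
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the smaller/canonical leaf side."""
    all_leaves = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canonical)
    return out


def bootstrap_support(
    labels: list[str],
    aligned: list[str],
    n_reps: int = 500,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Support on an internal edge is the percentage of ``n_reps`` replicate
    trees (columns resampled with replacement, seeded) whose topology
    contains the same leaf bipartition.  Reproducible given the seed and
    invariant to taxon input order (the resampling stream depends only on
    the seed and alignment length).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = len(aligned[0]) if aligned else 0
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(pairwise_distance(labels, aligned, model))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    sorted_labels = [labels[i] for i in order]
    sorted_seqs = [aligned[i] for i in order]
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(s[c] for c in cols) for s in sorted_seqs]
        rep = nj_tree(pairwise_distance(sorted_labels, resampled, model))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        other = frozenset(tree.leaf_names()) - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts[canonical] / n_reps
    return tree


def region_vs_whole_report(
    labels: list[str],
    aligned: list[str],
    bait_columns: tuple[int, int],
    model: str = "poisson",
) -> pd.DataFrame:
    """Whole-alignment vs bait-column distances and their per-pair ratio.

    ``bait_columns`` is the 1-based inclusive column window of the bait in
    the alignment frame.  The ratio bait/whole is NaN where the whole-
    alignment distance is zero (identical sequences) or the bait window is
    all-gap for the pair.
    """
    lo, hi = bait_columns
    if not (1 <= lo <= hi <= len(aligned[0])):
        raise ValueError("bait column window outside alignment")
    bait = [s[lo - 1 : hi] for s in aligned]
    d_whole = pairwise_distance(labels, aligned, model)
    d_bait = pairwise_distance(labels, bait, model)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            w = d_whole.values[i, j]
            b = d_bait.values[i, j]
            ratio = b / w if w > 0 and not np.isnan(b) else float("nan")
            rows.append(
                {
                    "taxon_a": labels[i],
                    "taxon_b": labels[j],
                    "whole": w,
                    "bait": b,
                    "ratio_bait_whole": ratio,
                    "model": model,
                }
            )
    return pd.DataFrame(rows)
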
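"""Neighbor-joining trees of satellite monomers with Jukes-Cantor distances.

Distances come from pairwise alignment: p is the proportion of differing
alignment columns, corrected by the Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3).  Trees are built with the Saitou-Nei
neighbor-joining algorithm, deterministic under ties (smallest label
pair), negative branch lengths clamped to zero, serialized as unrooted
newick with a trifurcating root.
"""

from __future__ import annotations

import io
import math
import warnings

import numpy as np
from skbio import TreeNode

from .align import mismatch_proportion

JC_SATURATION = 0.75


def jc_distance(p: float, d_max: float | None = None) -> float:
    """Jukes-Cantor distance for a mismatch proportion ``p``.

    ``p`` must lie in [0, 0.75); at or beyond 0.75 the correction is
    undefined (saturation) and either raises or, when ``d_max`` is given,
    returns the cap.
    """
    if not 0.0 <= p:
        raise ValueError(f"mismatch proportion out of range: {p}")
    if p >= JC_SATURATION:
        if d_max is not None:
            return d_max
        raise ValueError(f"mismatch proportion {p} >= 0.75: Jukes-Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_inverse(d: float) -> float:
    """Expected mismatch proportion at Jukes-Cantor distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


class DistanceMatrix:
    """Symmetric labelled distance matrix."""

    def __init__(self, labels: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (matrix < 0).any() or not np.isfinite(matrix).all():
            raise ValueError("distances must be finite and non-negative")
        self.labels = list(labels)
        self.matrix = matrix

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.matrix[i, j])


def pairwise_distances(
    sequences: list[str],
    labels: list[str] | None = None,
    d_max: float = 5.0,
) -> DistanceMatrix:
    """Jukes-Cantor distance matrix from pairwise alignments.

    Saturated pairs (p >= 0.75) are capped at ``d_max`` with a warning.
    """
    n = len(sequences)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    labels = labels if labels is not None else [f"m{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = mismatch_proportion(sequences[i], sequences[j])
            if p >= JC_SATURATION:
                warnings.warn(
                    f"saturated pair ({labels[i]}, {labels[j]}): p={p:.3f}, capping at {d_max}"
                )
                d = d_max
            else:
                d = jc_distance(p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Q-criterion ties are broken by the smallest (representative label)
    pair, where a cluster is represented by its lexicographically smallest
    leaf; negative branch lengths are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.copy()
    nodes = [f"{_quote(l)}" for l in dm.labels]  # newick fragments
    keys = list(dm.labels)  # tie-break representatives

    while len(nodes) > 3:
        m = len(nodes)
        total = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - total[i] - total[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _k, i, j = best
        li = 0.5 * d[i, j] + (total[i] - total[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        merged_key = min(keys[i], keys[j])

        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [merged]
        keys = [keys[k] for k in keep] + [merged_key]

    a, b, c = d[0, 1], d[0, 2], d[1, 2]
    la = max((a + b - c) / 2, 0.0)
    lb = max((a + c - b) / 2, 0.0)
    lc = max((b + c - a) / 2, 0.0)
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def parse_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets under every edge of the (unrooted) tree."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        out.append(tips)
    return out


def topologies_equal(newick_a: str, newick_b: str) -> bool:
    """Unrooted topological identity via matching non-trivial bipartitions."""
    ta, tb = parse_newick(newick_a), parse_newick(newick_b)
    leaves_a = frozenset(t.name for t in ta.tips())
    leaves_b = frozenset(t.name for t in tb.tips())
    if leaves_a != leaves_b:
        return False

    def splits(tree, leaves):
        out = set()
        for part in bipartitions(tree):
            if 1 < len(part) < len(leaves) - 1:
                out.add(min(part, leaves - part, key=sorted))
        return out

    return splits(ta, leaves_a) == splits(tb, leaves_b)


def clade_partition_check(
    newick: str, groups: dict[str, str]
) -> tuple[bool, float]:
    """Does some edge bipartition the tree into the two label groups?

    Returns (exact, purity): ``exact`` is True when an edge separates the
    groups perfectly; ``purity`` is the best achievable bipartition
    agreement over all edges (fraction of leaves on the "right" side).
    """
    tree = parse_newick(newick)
    leaves = frozenset(t.name for t in tree.tips())
    values = sorted(set(groups.values()))
    if len(values) != 2:
        raise ValueError("need exactly two groups")
    g1 = frozenset(l for l in leaves if groups[l] == values[0])
    g2 = leaves - g1
    n = len(leaves)
    exact = False
    purity = 0.0
    for side in bipartitions(tree):
        other = leaves - side
        if side == g1 or side == g2:
            exact = True
        agree = max(
            len(side & g1) + len(other & g2),
            len(side & g2) + len(other & g1),
        ) / n
        purity = max(purity, agree)
    return exact, purity
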
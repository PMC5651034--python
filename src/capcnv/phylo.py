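"""Neighbor-joining trees with bootstrap support for gene-copy alignments.

Distances are p-distances (mismatch fraction over sites ungapped in both
sequences); trees are built by the Saitou-Nei agglomeration with the
Studier-Keppler Q-criterion, ties broken deterministically by the lowest
index pair, and negative branch lengths clamped to zero (flagged on the
tree). Bootstrap support of each internal bipartition of the full-data tree
is the percentage of column-resampled replicates containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core import ValidationError


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences with unique taxon names."""

    names: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 3:
            raise ValidationError("alignment needs at least 3 taxa")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("taxon names must be unique")
        if len({len(s) for s in self.seqs}) != 1:
            raise ValidationError("sequences must have equal length")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, self.length)
        seqs = tuple(
            "".join(s[c] for c in cols) for s in self.seqs
        )
        return Alignment(self.names, seqs)


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise mismatch fractions ignoring sites gapped in either taxon."""
    arr = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in alignment.seqs]
    )
    gap = (arr == ord("-")) | (arr == ord("N"))
    n = len(alignment.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable sites between {alignment.names[i]} "
                    f"and {alignment.names[j]}"
                )
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / m
    return DistanceMatrix(d, ids=list(alignment.names))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    Returns an unrooted tree (trifurcating root). Sets ``tree.clamped`` if
    any negative branch length was clamped to zero.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i_d) for i_d in dm.ids]
    D = d.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among minima for determinism
        flat = np.flatnonzero(np.isclose(q, q.min()))
        i, j = sorted(divmod(int(flat[0]), m))
        li = clamp(D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dk = (D[i, :] + D[j, :] - D[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp((d01 + d02 - d12) / 2)
    l1 = clamp((d01 + d12 - d02) / 2)
    l2 = clamp((d02 + d12 - d01) / 2)
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    root = TreeNode(children=list(nodes))
    root.clamped = clamped
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge splits as canonical tip subsets of an unrooted tree."""
    tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue  # trivial split
        other = tips - side
        out.add(min(side, other, key=lambda s: sorted(s)))
    return out


def bootstrap_support(
    alignment: Alignment,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    outgroup: str | None = None,
) -> TreeNode:
    """NJ tree with per-internal-edge bootstrap percentages as node names.

    Columns are resampled with replacement ``reps`` times; each internal
    bipartition of the full-data tree is scored by the percentage of
    replicate trees containing it. If ``outgroup`` is given, the returned
    tree is rooted at that tip for display.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    full = neighbor_joining(p_distance_matrix(alignment))
    counts: dict[frozenset[str], int] = {
        bp: 0 for bp in bipartitions(full)
    }
    for _ in range(reps):
        rep_tree = neighbor_joining(
            p_distance_matrix(alignment.resample_columns(rng))
        )
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    tips = frozenset(t.name for t in full.tips())
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        key = min(side, tips - side, key=lambda s: sorted(s))
        node.name = f"{100.0 * counts[key] / reps:g}"
    if outgroup is not None:
        full = root_at_tip(full, outgroup)
    return full


def root_at_tip(tree: TreeNode, tip_name: str) -> TreeNode:
    tip = tree.find(tip_name)
    return tree.root_at(tip.parent)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


__all__ = [
    "Alignment",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "root_at_tip",
    "write_newick",
]
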
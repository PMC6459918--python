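"""Alignment-based distance matrices and neighbour-joining trees.

A desk-scale route from protein families to trees: all-vs-all affine-gap
global alignments give identity-based distances (d = 1 − identity/100),
and neighbour joining — exact on additive matrices — turns them into an
unrooted tree with branch lengths, written as Newick.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .coevolution import SubstitutionMatrix, blosum62, global_align


def distance_matrix(
    seqs: Sequence[tuple[str, str]],
    matrix: SubstitutionMatrix | None = None,
    **align_kwargs,
) -> DistanceMatrix:
    """All-vs-all alignment distances, d(i, j) = 1 − pct_identity/100.

    Each unordered pair is aligned once, so the matrix is symmetric by
    construction with a zero diagonal. Duplicate ids are an error.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if matrix is None:
        matrix = blosum62()
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i][1], seqs[j][1], matrix, **align_kwargs)
            d[i, j] = d[j, i] = 1.0 - aln.pct_identity / 100.0
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a distance matrix.

    Standard Saitou–Nei agglomeration with deterministic tie-breaking
    (the lexicographically lowest index pair attaining the minimum Q).
    Negative branch-length estimates are clamped to zero with a warning.
    The returned tree is the usual rooted representation of an unrooted
    topology; on additive matrices leaf-to-leaf path lengths reproduce
    the input distances.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]

    def _attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        if length < 0:
            warnings.warn(
                f"negative NJ branch length {length:.6g} clamped to 0",
                stacklevel=3,
            )
            length = 0.0
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 2:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # row-major: lowest pair
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = TreeNode()
        _attach(parent, nodes[i], li)
        _attach(parent, nodes[j], lj)
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([
            np.hstack([[0.0], dnew[keep]]),
            np.hstack([dnew[keep][:, None], D[np.ix_(keep, keep)]]),
        ])
        nodes = [parent] + [nodes[x] for x in keep]

    root = TreeNode()
    _attach(root, nodes[0], D[0, 1])
    _attach(root, nodes[1], 0.0)
    return root
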
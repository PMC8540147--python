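"""Distance-based ordination and clustering: IBS distances, PCoA, NJ trees.

PCoA follows the Gower construction: eigendecomposition of the
double-centred matrix -1/2 J (D o D) J.  Coordinates are built from the
positive eigenvalues only; percent variance per axis is the eigenvalue's
share of the sum of positive eigenvalues, and the total magnitude of any
negative eigenvalues is kept as a diagnostic.  Eigenvector signs are fixed
by making the first nonzero loading positive, so output is deterministic.

The neighbor-joining implementation uses the Saitou-Nei Q-criterion with
ties broken by the smallest (row, column) index pair; on additive distance
matrices the tree's path lengths reproduce the input exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix

__all__ = ["ibs_distance", "PCoA", "pcoa", "nj_tree", "tree_distance_matrix"]


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - identity-by-state proportion between individuals.

    d(i, j) = 1 - mean over shared called loci of (2 - |g_i - g_j|) / 2.
    Raises if a pair shares no called locus.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    n = gm.n_samples
    g = gm.dosages.astype(np.int16)
    called = ~gm.missing_mask
    d = np.zeros((n, n))
    for i in range(n - 1):
        shared = called[i] & called[i + 1 :]
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            j = i + 1 + int(np.argmax(n_shared == 0))
            raise ValueError(
                f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} "
                "share no called loci"
            )
        sim = ((2 - np.abs(g[i] - g[i + 1 :])) * shared).sum(axis=1) / (2.0 * n_shared)
        d[i, i + 1 :] = d[i + 1 :, i] = 1.0 - sim
    return DistanceMatrix(d, list(gm.sample_ids))


class PCoA(BaseEstimator):
    """Principal coordinate analysis of a distance matrix.

    Parameters
    ----------
    n_axes : int or None
        Number of leading axes to keep (None = all positive-eigenvalue axes).

    Attributes (after fit)
    ----------------------
    coordinates_ : DataFrame (labels x axes, columns PCo1, PCo2, ...).
    eigenvalues_ : positive eigenvalues, descending.
    percent_variance_ : 100 * eigenvalue / sum(positive eigenvalues).
    negative_eigenvalue_mass_ : sum of |negative eigenvalues| (diagnostic).
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, dm: DistanceMatrix, y=None) -> "PCoA":
        d = np.asarray(dm.data, dtype=float)
        m = d.shape[0]
        if m < 3:
            raise ValueError("PCoA needs at least 3 points")
        a = -0.5 * d * d
        row = a.mean(axis=1, keepdims=True)
        gmat = a - row - row.T + a.mean()
        eigval, eigvec = np.linalg.eigh(gmat)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        tol = 1e-10 * max(1.0, np.abs(eigval).max())
        pos = eigval > tol
        if not pos.any():
            raise ValueError("degenerate input: no positive eigenvalues")
        self.negative_eigenvalue_mass_ = float(np.abs(eigval[eigval < -tol]).sum())
        lam = eigval[pos]
        vec = eigvec[:, pos]
        # deterministic sign: first nonzero loading of each axis positive
        for k in range(vec.shape[1]):
            nz = np.flatnonzero(np.abs(vec[:, k]) > 1e-12)
            if nz.size and vec[nz[0], k] < 0:
                vec[:, k] = -vec[:, k]
        coords = vec * np.sqrt(lam)
        k = lam.size if self.n_axes is None else min(self.n_axes, lam.size)
        self.eigenvalues_ = lam[:k]
        self.percent_variance_ = 100.0 * lam[:k] / lam.sum()
        self.coordinates_ = pd.DataFrame(
            coords[:, :k],
            index=list(dm.ids),
            columns=[f"PCo{i + 1}" for i in range(k)],
        )
        return self

    def fit_transform(self, dm: DistanceMatrix, y=None) -> pd.DataFrame:
        return self.fit(dm).coordinates_


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoA:
    """Functional wrapper: returns a fitted :class:`PCoA`."""
    return PCoA(n_axes=n_axes).fit(dm)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance matrix.

    Saitou-Nei agglomeration; Q-matrix ties broken at the smallest
    (row, column) pair; negative branch lengths clamped to 0.
    """
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    n = d.shape[0]
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(label)) for label in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first minimum = smallest (row, col)
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, length)
    return TreeNode(children=list(nodes))


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity oracle)."""
    return tree.tip_tip_distances()
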
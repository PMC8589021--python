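"""Jaccard dissimilarity, neighbor-joining trees and principal coordinates.

The Jaccard dissimilarity between two fingerprints is ``1 - a / (a + b + c)``
over the columns where both samples' locus blocks were scored (a = shared
presences, b/c = presences unique to either side); joint absences do not
enter.  Trees are built with canonical Saitou-Nei neighbor joining using the
Studier-Keppler Q-criterion, and PCoA is classical metric MDS via Gower
double-centering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotype_io import AlleleMatrix, ValidationError

PathLike = Union[str, Path]

_NEWICK_UNSAFE = set(" \t\n()[]':;,")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities; NaN marks undefined pairs."""

    ids: tuple[str, ...]
    values: np.ndarray
    n_shared_columns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix is not symmetric")
        defined = ~np.isnan(v)
        if (v[defined] < -1e-12).any() or (v[defined] > 1 + 1e-12).any():
            raise ValidationError("distances must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_undefined_pairs(self) -> int:
        mask = np.isnan(self.values)
        return int(np.triu(mask, k=1).sum())

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (id1, id2, d, n_columns)."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "d": self.values[i, j],
                        "n_columns": (
                            int(self.n_shared_columns[i, j])
                            if self.n_shared_columns is not None
                            else -1
                        ),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimilarityMatrix:
    """Elementwise ``1 - d`` companion of a DistanceMatrix."""

    ids: tuple[str, ...]
    values: np.ndarray
    n_shared_columns: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.ids)


def _pairwise_jaccard(
    presence_a: np.ndarray,
    valid_a: np.ndarray,
    presence_b: np.ndarray,
    valid_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jaccard dissimilarity between all rows of a and all rows of b.

    Returns (d, n_shared_columns, union_size); d is NaN where the union of
    presences over co-scored columns is empty.
    """
    xa = (presence_a & valid_a).astype(np.float64)
    xb = (presence_b & valid_b).astype(np.float64)
    va = valid_a.astype(np.float64)
    vb = valid_b.astype(np.float64)
    a = xa @ xb.T
    union = xa @ vb.T + va @ xb.T - a
    n_shared = (va @ vb.T).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - a / union
    d[union == 0] = np.nan
    return d, n_shared, union


def jaccard_matrix(m: AlleleMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarities with pairwise-complete block handling."""
    if m.n_samples < 2:
        raise ValidationError("jaccard_matrix requires at least two samples")
    presence = m.presence()
    valid = m.column_scored()
    d, n_shared, _ = _pairwise_jaccard(presence, valid, presence, valid)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float non-associativity
    return DistanceMatrix(ids=m.sample_ids, values=d, n_shared_columns=n_shared)


def cross_jaccard(a: AlleleMatrix, b: AlleleMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Jaccard dissimilarity between every sample of ``a`` and of ``b``.

    Both matrices must share a panel (align with genotype_io.align_panels
    first if they do not).  Returns (d, n_shared_columns), shape (n_a, n_b).
    """
    if a.panel != b.panel:
        raise ValidationError("cross_jaccard requires identical panels")
    d, n_shared, _ = _pairwise_jaccard(
        a.presence(), a.column_scored(), b.presence(), b.column_scored()
    )
    return d, n_shared


def similarity(dm: DistanceMatrix) -> SimilarityMatrix:
    """Elementwise 1 - d; undefined pairs stay NaN."""
    return SimilarityMatrix(
        ids=dm.ids,
        values=1.0 - dm.values,
        n_shared_columns=dm.n_shared_columns,
    )


def write_distance_matrix(dm: DistanceMatrix, path: PathLike, long: bool = False) -> None:
    if long:
        dm.to_long().to_csv(path, index=False)
    else:
        dm.to_dataframe().to_csv(path, index_label="id")


def read_distance_matrix(path: PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column ids differ")
    return DistanceMatrix(
        ids=tuple(str(i) for i in df.index), values=df.to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves are the nodes listed in ``leaf_labels``; internal nodes have
    degree 3 except in degenerate small trees.
    """

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    n_negative_clamped: int = 0

    @property
    def leaves(self) -> tuple[int, ...]:
        return tuple(sorted(self.leaf_labels))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.leaf_labels[i] for i in self.leaves)

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, length in nbrs:
                if u < v:
                    out.append((u, v, length))
        return out

    def path_lengths(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf-to-leaf patristic distances (labels in leaf order)."""
        leaves = self.leaves
        index = {node: i for i, node in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))
        for start in leaves:
            seen = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, length in self.adjacency[u]:
                    if v not in seen:
                        seen[v] = seen[u] + length
                        stack.append(v)
            for leaf, total in seen.items():
                if leaf in index:
                    dist[index[start], index[leaf]] = total
        return tuple(self.leaf_labels[i] for i in leaves), dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf-label side not containing the
        lexicographically smallest label (a canonical representation)."""
        ref = min(self.leaf_labels.values())
        splits: set[frozenset[str]] = set()
        for u, v, _ in self.edges():
            side = self._side_labels(v, u)
            if 1 < len(side) < len(self.leaf_labels) - 1:
                if ref in side:
                    all_labels = set(self.leaf_labels.values())
                    side = all_labels - side
                splits.add(frozenset(side))
        return splits

    def _side_labels(self, start: int, blocked: int) -> set[str]:
        seen = {start, blocked}
        stack = [start]
        labels = set()
        while stack:
            u = stack.pop()
            if u in self.leaf_labels:
                labels.add(self.leaf_labels[u])
            for v, _ in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return labels

    def to_newick(self) -> str:
        root = max(self.adjacency)  # last-created internal node
        return _newick_subtree(self, root, None) + ";"


def _quote_label(label: str) -> str:
    if not label or _NEWICK_UNSAFE & set(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_subtree(t: PhyloTree, node: int, parent: Optional[int]) -> str:
    children = [(v, length) for v, length in t.adjacency[node] if v != parent]
    if not children:
        return _quote_label(t.leaf_labels[node])
    parts = [
        _newick_subtree(t, v, node) + f":{length:.10g}" for v, length in children
    ]
    return "(" + ",".join(parts) + ")"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Deterministic: ties in Q are broken by the lowest (row, column) index pair
    in the current node order (input order, internal nodes appended).
    Negative branch-length estimates are clamped to 0 and counted.
    """
    n = dm.n
    if n < 3:
        raise ValidationError("nj_tree requires at least three samples")
    if np.isnan(dm.values).any():
        raise ValidationError(
            "distance matrix has undefined entries; impute or remove those "
            "samples before building a tree"
        )
    cur = dm.values.astype(float).copy()
    active = list(range(n))
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = dict(enumerate(dm.ids))
    next_id = n
    clamped = 0

    def _add_edge(u: int, v: int, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))

    while len(active) > 2:
        size = len(active)
        r = cur.sum(axis=1)
        q = (size - 2) * cur - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order = tie rule
        i, j = divmod(flat, size)
        if i > j:
            i, j = j, i
        dij = cur[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (size - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        _add_edge(u, active[i], li)
        _add_edge(u, active[j], lj)
        d_new = 0.5 * (cur[i, :] + cur[j, :] - dij)
        keep = [k for k in range(size) if k not in (i, j)]
        nxt = np.empty((size - 1, size - 1))
        nxt[:-1, :-1] = cur[np.ix_(keep, keep)]
        nxt[-1, :-1] = d_new[keep]
        nxt[:-1, -1] = d_new[keep]
        nxt[-1, -1] = 0.0
        cur = nxt
        active = [active[k] for k in keep] + [u]

    _add_edge(active[0], active[1], cur[0, 1])
    return PhyloTree(
        adjacency=adjacency, leaf_labels=leaf_labels, n_negative_clamped=clamped
    )


def write_newick(t: PhyloTree, path: PathLike) -> None:
    Path(path).write_text(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Classical-MDS embedding of a distance matrix."""

    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variation: np.ndarray
    negative_eigenvalue_total: float = 0.0
    degenerate: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Gower double-centering of -d^2/2, eigendecomposition, sqrt scaling.

    Percent variation uses only positive eigenvalues in the denominator;
    negative eigenvalues (non-Euclidean input) are summed separately.
    """
    if n_axes < 1:
        raise ValidationError("n_axes must be >= 1")
    if np.isnan(dm.values).any():
        raise ValidationError("pcoa requires a fully defined distance matrix")
    n = dm.n
    d2 = dm.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-12 * max(1.0, float(np.abs(eigval).max(initial=0.0)))
    positive = eigval > tol
    pos_sum = float(eigval[positive].sum())
    neg_total = float(-eigval[eigval < -tol].sum())

    if pos_sum == 0.0:
        return Ordination(
            ids=dm.ids,
            coordinates=np.zeros((n, n_axes)),
            eigenvalues=eigval,
            percent_variation=np.zeros(n_axes),
            negative_eigenvalue_total=neg_total,
            degenerate=True,
        )

    k = min(n_axes, int(positive.sum()))
    coords = np.zeros((n, n_axes))
    coords[:, :k] = eigvec[:, :k] * np.sqrt(eigval[:k])
    percent = np.zeros(n_axes)
    percent[:k] = eigval[:k] / pos_sum * 100.0
    return Ordination(
        ids=dm.ids,
        coordinates=coords,
        eigenvalues=eigval,
        percent_variation=percent,
        negative_eigenvalue_total=neg_total,
    )
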
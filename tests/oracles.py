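"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (python loops, sets, explicit sums) and
shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def brute_jaccard(m, i: int, j: int) -> tuple[float, int]:
    """Set-based Jaccard dissimilarity between rows i and j of an AlleleMatrix.

    Walks marker blocks cell by cell; a block with any 9 is skipped for that
    sample.  Returns (distance, n co-scored columns); distance is NaN when the
    union of presences is empty.
    """
    present_i: set[int] = set()
    present_j: set[int] = set()
    n_shared_cols = 0
    col = 0
    for mk in m.panel.markers:
        width = mk.n_alleles
        block_i = [int(m.scores[i, col + c]) for c in range(width)]
        block_j = [int(m.scores[j, col + c]) for c in range(width)]
        ok_i = all(v != 9 for v in block_i)
        ok_j = all(v != 9 for v in block_j)
        if ok_i and ok_j:
            n_shared_cols += width
            for c in range(width):
                if block_i[c] == 1:
                    present_i.add(col + c)
                if block_j[c] == 1:
                    present_j.add(col + c)
        col += width
    union = present_i | present_j
    if not union:
        return float("nan"), n_shared_cols
    inter = present_i & present_j
    return 1.0 - len(inter) / len(union), n_shared_cols


def brute_pic(p) -> float:
    """Literal double-sum expansion of the Botstein PIC statistic."""
    p = list(p)
    n = len(p)
    total = 1.0
    for pi in p:
        total -= pi**2
    for i in range(n - 1):
        for j in range(i + 1, n):
            total -= 2.0 * p[i] ** 2 * p[j] ** 2
    return total


def equal_frequency_pic(n: int) -> float:
    """Closed form for n equally frequent alleles: 1 - 1/n - (n-1)/n^3."""
    return 1.0 - 1.0 / n - (n - 1) / n**3


class AdditiveTree:
    """Random unrooted binary tree with branch lengths, built by sequential
    leaf attachment, exposing its leaf distance matrix and split set."""

    def __init__(self, rng: np.random.Generator, n_leaves: int,
                 min_len: float = 0.1, max_len: float = 1.0):
        assert n_leaves >= 3
        self.labels = [f"L{i}" for i in range(n_leaves)]
        self.adj: dict[int, list[tuple[int, float]]] = {}
        self._next = n_leaves

        def rand_len() -> float:
            return float(rng.uniform(min_len, max_len))

        # start from the unique 3-leaf star
        center = self._new_node()
        for leaf in range(3):
            self._add_edge(leaf, center, rand_len())
        for leaf in range(3, n_leaves):
            u, v, length = self._random_edge(rng)
            self._remove_edge(u, v)
            w = self._new_node()
            t = float(rng.uniform(0.2, 0.8))
            self._add_edge(u, w, length * t)
            self._add_edge(w, v, length * (1.0 - t))
            self._add_edge(w, leaf, rand_len())
        self.n_leaves = n_leaves

    def _new_node(self) -> int:
        node = self._next
        self._next += 1
        self.adj[node] = []
        return node

    def _add_edge(self, u: int, v: int, length: float) -> None:
        self.adj.setdefault(u, []).append((v, length))
        self.adj.setdefault(v, []).append((u, length))

    def _remove_edge(self, u: int, v: int) -> None:
        self.adj[u] = [(x, l) for x, l in self.adj[u] if x != v]
        self.adj[v] = [(x, l) for x, l in self.adj[v] if x != u]

    def _random_edge(self, rng) -> tuple[int, int, float]:
        edges = [
            (u, v, l) for u in self.adj for v, l in self.adj[u] if u < v
        ]
        u, v, l = edges[int(rng.integers(len(edges)))]
        return u, v, l

    def distance_matrix(self) -> np.ndarray:
        n = self.n_leaves
        out = np.zeros((n, n))
        for start in range(n):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                x = stack.pop()
                for y, l in self.adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + l
                        stack.append(y)
            for leaf in range(n):
                out[start, leaf] = dist[leaf]
        return out

    def splits(self) -> set[frozenset[str]]:
        """Canonical non-trivial bipartitions (side without label 'L0')."""
        all_labels = set(self.labels)
        out: set[frozenset[str]] = set()
        for u in self.adj:
            for v, _ in self.adj[u]:
                if u >= v:
                    continue
                side = self._side(v, u)
                if 1 < len(side) < self.n_leaves - 1:
                    if "L0" in side:
                        side = all_labels - side
                    out.add(frozenset(side))
        return out

    def _side(self, start: int, blocked: int) -> set[str]:
        seen = {start, blocked}
        stack = [start]
        labels: set[str] = set()
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                labels.add(self.labels[x])
            for y, _ in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return labels
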
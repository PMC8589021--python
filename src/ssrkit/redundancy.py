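"""Duplicate-group detection and collection pruning at a similarity threshold.

A pair of samples is "duplicate-linked" when their similarity (1 - Jaccard
dissimilarity) reaches the threshold.  Groups are connected components of the
resulting graph (single linkage) or threshold-cut complete-linkage clusters;
one lexicographically smallest representative per group is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import AlleleMatrix, ValidationError, subset
from .distance_tree import DistanceMatrix

LINKAGES = ("single", "complete")


@dataclass
class DuplicateGroups:
    """Partition of sample ids into putative duplicate groups."""

    threshold: float
    linkage: str
    groups: list[tuple[str, ...]]
    representatives: list[str]
    pruned_ids: list[str]
    n_total: int
    n_undefined_pairs: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_removed(self) -> int:
        return self.n_total - len(self.pruned_ids)

    @property
    def percent_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_total if self.n_total else 0.0

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for g, members in enumerate(self.groups):
            rep = self.representatives[g]
            for sid in members:
                rows.append(
                    {"sample_id": sid, "group": g, "representative": rep,
                     "retained": sid == rep}
                )
        return pd.DataFrame(rows)


def find_duplicates(
    dm: DistanceMatrix, threshold: float, linkage: str = "single"
) -> DuplicateGroups:
    """Group samples whose pairwise similarity reaches ``threshold``.

    Undefined distances never link samples.  Representatives are the
    lexicographically smallest id of each group, making the outcome
    independent of input row order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")

    n = dm.n
    values = dm.values.copy()
    undefined = np.isnan(values)
    n_undefined = int(np.triu(undefined, k=1).sum())

    if linkage == "single":
        sim = 1.0 - values
        adj = (sim >= threshold) & ~undefined
        np.fill_diagonal(adj, False)
        _, labels = connected_components(csr_matrix(adj), directed=False)
    else:
        condensed = values[np.triu_indices(n, k=1)]
        condensed = np.where(np.isnan(condensed), 2.0, condensed)  # never merges
        z = scipy_linkage(condensed, method="complete")
        labels = fcluster(z, t=1.0 - threshold + 1e-12, criterion="distance")

    groups_by_label: dict[int, list[str]] = {}
    for sid, lab in zip(dm.ids, labels):
        groups_by_label.setdefault(int(lab), []).append(sid)
    # order groups by their smallest member for a stable, order-free output
    ordered = sorted(groups_by_label.values(), key=lambda members: min(members))
    groups = [tuple(members) for members in ordered]
    representatives = [min(members) for members in groups]
    rep_set = set(representatives)
    pruned_ids = [sid for sid in dm.ids if sid in rep_set]
    return DuplicateGroups(
        threshold=threshold,
        linkage=linkage,
        groups=groups,
        representatives=representatives,
        pruned_ids=pruned_ids,
        n_total=n,
        n_undefined_pairs=n_undefined,
    )


def prune(m: AlleleMatrix, groups: DuplicateGroups) -> AlleleMatrix:
    """Subset the matrix to one representative per duplicate group.

    Row order follows the original matrix.  Raises when the grouping was not
    computed from this matrix's samples.
    """
    grouped = {sid for members in groups.groups for sid in members}
    if grouped != set(m.sample_ids):
        raise ValidationError(
            "duplicate groups do not match the matrix samples (stale grouping?)"
        )
    return subset(m, groups.pruned_ids)


def similarity_distribution(
    dm: DistanceMatrix,
    bins: int = 100,
    thresholds: Sequence[float] = (),
) -> tuple[pd.DataFrame, dict[float, tuple[int, float]]]:
    """Histogram of pairwise distances over [0, 1].

    Also returns, per requested similarity threshold, the count and fraction
    of defined pairs at similarity >= threshold.
    """
    condensed = dm.condensed()
    defined = condensed[~np.isnan(condensed)]
    counts, edges = np.histogram(defined, bins=bins, range=(0.0, 1.0))
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    n_pairs = defined.size
    above: dict[float, tuple[int, float]] = {}
    for t in thresholds:
        k = int((1.0 - defined >= t).sum())
        above[float(t)] = (k, k / n_pairs if n_pairs else float("nan"))
    return hist, above
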
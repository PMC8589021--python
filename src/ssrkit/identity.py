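"""Clonal identity verification and cross-collection reconciliation.

Two tools: paired true-to-type checks (e.g. greenhouse mother plant vs its
in-vitro culture) and reconciliation of a query collection against a
reference collection via declared-transfer / name-match links and a
uniqueness threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import genotype_io
from .genotype_io import (
    AlleleMatrix,
    UnknownSampleError,
    ValidationError,
    make_sample_id,
)
from .distance_tree import cross_jaccard

PathLike = Union[str, Path]

VERDICTS = ("TTT_match", "nTTT_mismatch", "indeterminate")
LINK_TYPES = ("declared_transfer", "name_match")
CATEGORIES = (
    "shared_match",
    "shared_mismatch",
    "name_match_genotype_match",
    "name_match_genotype_mismatch",
    "unlinked_hit",
    "unique",
)


# ---------------------------------------------------------------------------
# paired verification
# ---------------------------------------------------------------------------

@dataclass
class PairVerdict:
    """Outcome of comparing two fingerprints of the same accession."""

    accession_id: str
    sample_a: str
    sample_b: str
    verdict: str
    n_loci_compared: int
    n_allele_mismatches: int
    per_marker: dict[str, int] = field(default_factory=dict)


@dataclass
class VerifySummary:
    n_pairs: int
    n_match: int
    n_mismatch: int
    n_indeterminate: int

    @property
    def mismatch_fraction(self) -> float:
        determinate = self.n_match + self.n_mismatch
        return self.n_mismatch / determinate if determinate else float("nan")

    @property
    def mismatch_percent(self) -> float:
        return 100.0 * self.mismatch_fraction


def _compare_fingerprints(
    m: AlleleMatrix, blocks: np.ndarray, i: int, j: int
) -> tuple[int, int, dict[str, int]]:
    """(loci compared, allele mismatches, per-marker mismatches) for rows i, j."""
    both = blocks[i] & blocks[j]
    n_loci = int(both.sum())
    mismatches: dict[str, int] = {}
    total = 0
    for k, mk in enumerate(m.panel.markers):
        if not both[k]:
            continue
        sl = m.panel.marker_slice(mk.name)
        diff = int((m.scores[i, sl] != m.scores[j, sl]).sum())
        if diff:
            mismatches[mk.name] = diff
            total += diff
    return n_loci, total, mismatches


def verify_pairs(
    m: AlleleMatrix,
    pairs: Sequence[tuple[str, str]],
    tolerance: int = 0,
    min_loci: int = 1,
) -> tuple[list[PairVerdict], VerifySummary]:
    """Classify each sample pair as matching, mismatching or indeterminate.

    Presence calls are compared over loci scored in both samples; a pair
    matches when its allele mismatches do not exceed ``tolerance`` and at
    least ``min_loci`` loci were co-scored.  The comparison is symmetric in
    pair order.
    """
    verdicts: list[PairVerdict] = []
    n_match = n_mismatch = n_indet = 0
    blocks = m.block_scored()
    index = {sid: i for i, sid in enumerate(m.sample_ids)}
    for sid_a, sid_b in pairs:
        try:
            i, j = index[sid_a], index[sid_b]
        except KeyError as exc:
            raise UnknownSampleError(str(exc.args[0])) from None
        n_loci, n_diff, per_marker = _compare_fingerprints(m, blocks, i, j)
        if n_loci < min_loci:
            verdict = "indeterminate"
            n_indet += 1
        elif n_diff <= tolerance:
            verdict = "TTT_match"
            n_match += 1
        else:
            verdict = "nTTT_mismatch"
            n_mismatch += 1
        acc_a, _ = genotype_io.split_sample_id(sid_a)
        verdicts.append(
            PairVerdict(
                accession_id=acc_a,
                sample_a=sid_a,
                sample_b=sid_b,
                verdict=verdict,
                n_loci_compared=n_loci,
                n_allele_mismatches=n_diff,
                per_marker=per_marker,
            )
        )
    summary = VerifySummary(
        n_pairs=len(verdicts),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_indeterminate=n_indet,
    )
    return verdicts, summary


def read_pairs(path: PathLike) -> list[tuple[str, str]]:
    """Read a pairs table: accession_id, sample_source_a, sample_source_b."""
    pairs = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"accession_id", "sample_source_a", "sample_source_b"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise genotype_io.FormatError(
                f"{path}: pairs table needs columns {sorted(required)}"
            )
        for row in reader:
            pairs.append(
                (
                    make_sample_id(row["accession_id"], row["sample_source_a"]),
                    make_sample_id(row["accession_id"], row["sample_source_b"]),
                )
            )
    return pairs


def write_pairs(pairs: Iterable[tuple[str, str]], path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession_id", "sample_source_a", "sample_source_b"])
        for sid_a, sid_b in pairs:
            acc_a, src_a = genotype_io.split_sample_id(sid_a)
            _, src_b = genotype_io.split_sample_id(sid_b)
            writer.writerow([acc_a, src_a, src_b])


# ---------------------------------------------------------------------------
# cross-collection reconciliation
# ---------------------------------------------------------------------------

@dataclass
class Link:
    query_id: str
    reference_id: str
    link_type: str

    def __post_init__(self) -> None:
        if self.link_type not in LINK_TYPES:
            raise ValidationError(
                f"link type must be one of {LINK_TYPES}, got {self.link_type!r}"
            )


@dataclass
class SampleReconciliation:
    query_id: str
    category: str
    best_hit: Optional[str]
    best_similarity: float
    linked_to: Optional[str] = None
    linked_similarity: float = float("nan")


@dataclass
class ReconciliationReport:
    records: list[SampleReconciliation]
    match_threshold: float
    uniqueness_threshold: float

    @property
    def counts(self) -> dict[str, int]:
        out = {cat: 0 for cat in CATEGORIES}
        for rec in self.records:
            out[rec.category] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": r.query_id,
                    "category": r.category,
                    "best_hit": r.best_hit,
                    "best_similarity": r.best_similarity,
                    "linked_to": r.linked_to,
                    "linked_similarity": r.linked_similarity,
                }
                for r in self.records
            ]
        )


def _aligned_similarities(
    query: AlleleMatrix, reference: AlleleMatrix
) -> np.ndarray:
    q, r = genotype_io.align_panels(query, reference)
    d, _ = cross_jaccard(q, r)
    return 1.0 - d


def reconcile(
    query: AlleleMatrix,
    reference: AlleleMatrix,
    links: Optional[Sequence[Link]] = None,
    match_threshold: float = 1.0,
    uniqueness_threshold: float = 0.95,
) -> ReconciliationReport:
    """Categorize each query sample against a reference collection.

    Linked queries (declared transfers or shared names) are judged against
    their declared counterpart at ``match_threshold``; the rest are unique
    when no reference sample reaches ``uniqueness_threshold`` similarity and
    otherwise reported with their best hit.
    """
    links = list(links or [])
    ref_index = {sid: i for i, sid in enumerate(reference.sample_ids)}
    query_index = {sid: i for i, sid in enumerate(query.sample_ids)}
    for link in links:
        if link.query_id not in query_index:
            raise UnknownSampleError(link.query_id)
        if link.reference_id not in ref_index:
            raise UnknownSampleError(link.reference_id)
    link_by_query: dict[str, Link] = {}
    for link in links:
        if link.query_id in link_by_query:
            raise ValidationError(f"multiple links for query {link.query_id!r}")
        link_by_query[link.query_id] = link

    sims = _aligned_similarities(query, reference)

    records: list[SampleReconciliation] = []
    for qi, qid in enumerate(query.sample_ids):
        row = sims[qi]
        finite = np.where(np.isnan(row), -np.inf, row)
        best = int(np.argmax(finite))
        best_sim = float(finite[best])
        best_hit = reference.sample_ids[best] if np.isfinite(best_sim) else None
        link = link_by_query.get(qid)
        if link is not None:
            linked_sim = float(row[ref_index[link.reference_id]])
            matched = linked_sim >= match_threshold and not np.isnan(linked_sim)
            if link.link_type == "declared_transfer":
                category = "shared_match" if matched else "shared_mismatch"
            else:
                category = (
                    "name_match_genotype_match"
                    if matched
                    else "name_match_genotype_mismatch"
                )
            records.append(
                SampleReconciliation(
                    query_id=qid,
                    category=category,
                    best_hit=best_hit,
                    best_similarity=best_sim,
                    linked_to=link.reference_id,
                    linked_similarity=linked_sim,
                )
            )
        else:
            category = "unique" if best_sim < uniqueness_threshold else "unlinked_hit"
            records.append(
                SampleReconciliation(
                    query_id=qid,
                    category=category,
                    best_hit=best_hit,
                    best_similarity=best_sim,
                )
            )
    return ReconciliationReport(
        records=records,
        match_threshold=match_threshold,
        uniqueness_threshold=uniqueness_threshold,
    )


def read_links(path: PathLike) -> list[Link]:
    links = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"query_id", "reference_id", "link_type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise genotype_io.FormatError(
                f"{path}: links table needs columns {sorted(required)}"
            )
        for row in reader:
            links.append(Link(row["query_id"], row["reference_id"], row["link_type"]))
    return links


def write_links(links: Iterable[Link], path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "reference_id", "link_type"])
        for link in links:
            writer.writerow([link.query_id, link.reference_id, link.link_type])


# ---------------------------------------------------------------------------
# nearest neighbors
# ---------------------------------------------------------------------------

def nearest_neighbors(
    query: AlleleMatrix,
    reference: AlleleMatrix,
    k: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Top-k reference samples per query by similarity.

    Also returns the union of all reference ids appearing in any top-k list
    (the "most similar" reference subset for joint tree building).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sims = _aligned_similarities(query, reference)
    k_eff = min(k, reference.n_samples)
    rows = []
    union: set[str] = set()
    for qi, qid in enumerate(query.sample_ids):
        row = np.where(np.isnan(sims[qi]), -np.inf, sims[qi])
        order = np.argsort(-row, kind="stable")[:k_eff]
        for rank, ri in enumerate(order, start=1):
            rid = reference.sample_ids[int(ri)]
            union.add(rid)
            rows.append(
                {
                    "query_id": qid,
                    "rank": rank,
                    "reference_id": rid,
                    "similarity": float(row[int(ri)]),
                }
            )
    table = pd.DataFrame(rows)
    union_ids = [sid for sid in reference.sample_ids if sid in union]
    return table, union_ids
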
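"""Per-marker and per-group diversity statistics for dominant polyploid scores.

Allele frequencies are estimated under the equal-dosage convention: a sample
presenting k alleles at a locus contributes weight 1/k to each presented
allele (dosage is unobservable in dominant polyploid scoring, so all presented
alleles are assumed equally dosed).  PIC uses the Botstein statistic
``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2`` and expected heterozygosity is
``1 - sum(p_i^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotype_io import AlleleMatrix, ValidationError

PathLike = Union[str, Path]

_GLOBAL_GROUP = "all"


@dataclass
class AlleleFrequencyTable:
    """Equal-dosage allele frequencies for one group of samples.

    ``frequencies[marker]`` is an array aligned with the panel's allele labels
    (or ``None`` when no sample in the group scored the marker);
    ``n_scored[marker]`` counts the samples contributing to it.
    """

    group: str
    allele_labels: dict[str, tuple[str, ...]]
    frequencies: dict[str, Optional[np.ndarray]]
    n_scored: dict[str, int]

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.frequencies)

    def defined(self, marker: str) -> bool:
        return self.frequencies[marker] is not None


@dataclass
class FstResult:
    """Among-group differentiation from expected heterozygosities."""

    grouping: str
    ht: float
    mean_hs: float
    value: float
    per_marker: pd.DataFrame
    clamped: bool = False
    excluded_markers: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def allele_counts(m: AlleleMatrix) -> pd.DataFrame:
    """Per-marker observed allele totals and mean presented alleles per sample.

    Only (sample, marker) blocks scored in full contribute.  Markers scored in
    zero samples get ``n_scored = 0`` and NaN means.
    """
    if m.n_samples < 1:
        raise ValidationError("allele_counts requires at least one sample")
    blocks = m.block_scored()
    presence = m.presence()
    rows = []
    for j, mk in enumerate(m.panel.markers):
        sl = m.panel.marker_slice(mk.name)
        scored = blocks[:, j]
        sub = presence[scored][:, sl]
        n_scored = int(scored.sum())
        if n_scored:
            total = int((sub.any(axis=0)).sum())
            mean = float(sub.sum(axis=1).mean())
        else:
            total, mean = 0, float("nan")
        rows.append(
            {
                "marker": mk.name,
                "total_alleles": total,
                "mean_alleles_per_individual": mean,
                "n_scored": n_scored,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    m: AlleleMatrix,
    groups: Optional[Mapping[str, str]] = None,
) -> dict[str, AlleleFrequencyTable]:
    """Equal-dosage frequency tables, one per group.

    ``groups`` maps sample ids to group labels; unmapped samples are skipped.
    With no grouping all samples form the single group ``"all"``.  Samples
    whose scored block presents zero alleles are excluded from that marker.
    """
    if groups is None:
        groups = {sid: _GLOBAL_GROUP for sid in m.sample_ids}
    labels = sorted(set(groups.values()))
    members = {
        g: np.array(
            [i for i, sid in enumerate(m.sample_ids) if groups.get(sid) == g],
            dtype=int,
        )
        for g in labels
    }
    blocks = m.block_scored()
    presence = m.presence().astype(float)
    allele_labels = {mk.name: mk.allele_labels for mk in m.panel.markers}

    out: dict[str, AlleleFrequencyTable] = {}
    for g in labels:
        idx = members[g]
        freqs: dict[str, Optional[np.ndarray]] = {}
        n_scored: dict[str, int] = {}
        for j, mk in enumerate(m.panel.markers):
            sl = m.panel.marker_slice(mk.name)
            if idx.size == 0:
                freqs[mk.name], n_scored[mk.name] = None, 0
                continue
            scored = idx[blocks[idx, j]]
            sub = presence[scored][:, sl]
            k = sub.sum(axis=1)
            usable = k > 0
            n = int(usable.sum())
            n_scored[mk.name] = n
            if n == 0:
                freqs[mk.name] = None
                continue
            weights = sub[usable] / k[usable, None]
            freqs[mk.name] = weights.mean(axis=0)
        out[g] = AlleleFrequencyTable(
            group=g, allele_labels=allele_labels, frequencies=freqs, n_scored=n_scored
        )
    return out


# ---------------------------------------------------------------------------
# PIC and expected heterozygosity
# ---------------------------------------------------------------------------

def pic_from_frequencies(p: np.ndarray) -> float:
    """Botstein PIC: ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``."""
    q = np.asarray(p, dtype=float) ** 2
    cross = 2.0 * np.sum(np.triu(np.outer(q, q), k=1))
    return float(1.0 - q.sum() - cross)


def pic(freqs: AlleleFrequencyTable) -> pd.Series:
    """Per-marker PIC; NaN where frequencies are undefined."""
    values = {
        marker: (pic_from_frequencies(p) if p is not None else float("nan"))
        for marker, p in freqs.frequencies.items()
    }
    return pd.Series(values, name="pic")


def expected_heterozygosity(freqs: AlleleFrequencyTable) -> tuple[pd.Series, float]:
    """Per-marker He = 1 - sum(p_i^2) plus the mean over defined markers."""
    values = {
        marker: (float(1.0 - np.sum(np.asarray(p) ** 2)) if p is not None else float("nan"))
        for marker, p in freqs.frequencies.items()
    }
    series = pd.Series(values, name="he")
    return series, float(series.dropna().mean())


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def fst(
    m: AlleleMatrix,
    groups: Mapping[str, str],
    grouping: str = "groups",
) -> FstResult:
    """(Ht - mean Hs) / Ht over markers usable in every group.

    Group Hs values are weighted by the number of scored samples; pooled
    frequencies use the same weights; markers are combined by Ht-weighted
    mean.  Negative estimates (sampling noise) are clamped to 0 and flagged.
    """
    tables = allele_frequencies(m, groups)
    labels = sorted(tables)
    if len(labels) < 2:
        raise ValidationError("fst requires at least two groups")

    rows = []
    excluded: list[str] = []
    for mk in m.panel.markers:
        name = mk.name
        ns = np.array([tables[g].n_scored[name] for g in labels], dtype=float)
        if (ns == 0).any():
            excluded.append(name)
            continue
        ps = np.vstack([tables[g].frequencies[name] for g in labels])
        pooled = (ns[:, None] * ps).sum(axis=0) / ns.sum()
        ht = float(1.0 - np.sum(pooled**2))
        hs = 1.0 - np.sum(ps**2, axis=1)
        mean_hs = float((ns * hs).sum() / ns.sum())
        value = (ht - mean_hs) / ht if ht > 0 else float("nan")
        rows.append({"marker": name, "ht": ht, "mean_hs": mean_hs, "fst": value})

    per_marker = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["ht", "mean_hs", "fst"]
    )
    usable = per_marker.dropna(subset=["fst"])
    if len(usable) == 0:
        raise ValidationError("fst: no marker is usable in every group")
    ht_sum = float(usable["ht"].sum())
    value = float((usable["ht"] * usable["fst"]).sum() / ht_sum)
    clamped = value < 0
    return FstResult(
        grouping=grouping,
        ht=float(usable["ht"].mean()),
        mean_hs=float(usable["mean_hs"].mean()),
        value=max(value, 0.0),
        per_marker=per_marker,
        clamped=clamped,
        excluded_markers=excluded,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def marker_summary(m: AlleleMatrix) -> pd.DataFrame:
    """Per-marker report: allele totals, mean alleles/individual, PIC and He."""
    counts = allele_counts(m)
    table = allele_frequencies(m)[_GLOBAL_GROUP]
    he, _ = expected_heterozygosity(table)
    return counts.join(pic(table)).join(he)


def write_marker_summary(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, float_format="%.6g")


def summarize_marker_table(df: pd.DataFrame) -> dict[str, float]:
    """Aggregate a per-marker summary table (mean/min/max of counts and PIC)."""
    out: dict[str, float] = {"n_markers": int(len(df))}
    out["mean_total_alleles"] = float(df["total_alleles"].mean())
    out["min_total_alleles"] = int(df["total_alleles"].min())
    out["max_total_alleles"] = int(df["total_alleles"].max())
    out["mean_pic"] = float(df["pic"].mean())
    out["min_pic"] = float(df["pic"].min())
    out["max_pic"] = float(df["pic"].max())
    if "mean_alleles_per_individual" in df:
        col = df["mean_alleles_per_individual"]
        out["mean_alleles_per_individual"] = float(col.mean())
        out["min_alleles_per_individual"] = float(col.min())
        out["max_alleles_per_individual"] = float(col.max())
    return out


def load_reference_marker_summary() -> pd.DataFrame:
    """Published per-marker summary values for the CIP 20-marker SSR panel.

    Columns: allele size range, total alleles, mean alleles per individual,
    PIC (CIP and USDA material) and repeat motif, indexed by marker name.
    """
    ref = resources.files("ssrkit") / "data" / "cip_ssr_panel_summary.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p).set_index("marker")
    return df.rename(columns={"pic_cip": "pic"})
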
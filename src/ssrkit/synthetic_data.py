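"""Synthetic polysomic SSR fingerprint collections with known ground truth.

The generator draws per-population allele-frequency spectra from a shared
base Dirichlet (between-population separation controlled by ``divergence``),
admixes individuals, draws ``ploidy`` allele copies per locus, and collapses
copies to dominant presence/absence.  Optional noise processes: clonal
duplication, per-allele scoring-error flips, whole-block missingness, and
whole-fingerprint label swaps for paired samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    ABSENT,
    MISSING,
    PRESENT,
    AccessionRecord,
    AlleleMatrix,
    Marker,
    MarkerPanel,
    ValidationError,
    make_sample_id,
)
from .identity import Link

PathLike = Union[str, Path]

_MIN_ALPHA = 1e-6  # Dirichlet parameters must stay strictly positive


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Full parameterization of the fingerprint simulator.

    Defaults are calibrated so that summary statistics of a simulated
    collection (allele counts, mean presented alleles per individual, PIC)
    fall in the bands observed for real hexaploid SSR panels.
    """

    n_markers: int = 20
    alleles_per_marker: Union[int, Sequence[int]] = 15
    K: int = 4
    dirichlet_concentration: float = 0.35
    divergence: float = 0.3
    admixture_alpha: float = 0.3
    ploidy: int = 6
    n_individuals: int = 100
    clone_rate: float = 0.0
    clone_copy_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0}
    )
    missing_rate: float = 0.0
    scoring_error_rate: float = 0.0
    label_swap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ConfigError("n_markers must be >= 1")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.ploidy < 2:
            raise ConfigError("ploidy must be >= 2")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        for name in ("clone_rate", "missing_rate", "scoring_error_rate",
                     "label_swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("dirichlet_concentration", "divergence", "admixture_alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        counts = self.allele_count_list()
        if any(c < 1 for c in counts):
            raise ConfigError("every marker needs at least one allele")
        if self.divergence > 0 and any(c < 2 for c in counts):
            raise ConfigError(
                "markers with fewer than 2 alleles cannot diverge between "
                "populations"
            )
        dist = dict(self.clone_copy_distribution)
        if dist:
            if any(c < 1 for c in dist):
                raise ConfigError("clone copy counts must be >= 1")
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ConfigError("clone_copy_distribution must sum to 1")

    def allele_count_list(self) -> list[int]:
        if isinstance(self.alleles_per_marker, int):
            return [self.alleles_per_marker] * self.n_markers
        counts = list(self.alleles_per_marker)
        if len(counts) != self.n_markers:
            raise ConfigError(
                f"alleles_per_marker has {len(counts)} entries for "
                f"{self.n_markers} markers"
            )
        return counts

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(data)
        if "clone_copy_distribution" in payload:
            payload["clone_copy_distribution"] = {
                int(k): float(v) for k, v in payload["clone_copy_distribution"].items()
            }
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SimulationConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: PathLike) -> None:
        data = asdict(self)
        data["clone_copy_distribution"] = dict(self.clone_copy_distribution)
        if not isinstance(data["alleles_per_marker"], int):
            data["alleles_per_marker"] = list(data["alleles_per_marker"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class GroundTruth:
    """Simulation bookkeeping enabling parameter-recovery tests."""

    samples: pd.DataFrame  # sample_id, individual, population, clone_group, ...
    ancestry: np.ndarray  # individuals x K
    population_frequencies: list[np.ndarray]  # per marker: K x n_alleles
    true_fingerprints: np.ndarray  # individuals x columns, pre-noise 0/1

    def population_of(self, sample_id: str) -> int:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        return int(row["population"].iloc[0])


@dataclass
class SimulationResult:
    matrix: AlleleMatrix
    records: list[AccessionRecord]
    truth: GroundTruth


@dataclass
class PairedFixture:
    matrix: AlleleMatrix
    records: list[AccessionRecord]
    pairs: list[tuple[str, str]]
    truth: GroundTruth

    @property
    def n_swapped(self) -> int:
        return int(self.truth.samples["swapped"].sum())


@dataclass
class TwoCollectionFixture:
    reference: AlleleMatrix
    query: AlleleMatrix
    links: list[Link]
    records: list[AccessionRecord]
    truth: pd.DataFrame  # per query sample: role, counterpart, link_error


# ---------------------------------------------------------------------------
# core generator
# ---------------------------------------------------------------------------

def _make_panel(config: SimulationConfig) -> MarkerPanel:
    markers = []
    for j, n_alleles in enumerate(config.allele_count_list()):
        base = 100 + 10 * j
        labels = tuple(str(base + 2 * a) for a in range(n_alleles))
        markers.append(
            Marker(
                name=f"SIM{j + 1:02d}",
                allele_labels=labels,
                size_range_bp=(int(labels[0]), int(labels[-1])),
            )
        )
    return MarkerPanel(markers=tuple(markers))


def _draw_population_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per marker, a K x A frequency matrix.

    Each population's spectrum is a Dirichlet draw centred on a shared base
    spectrum with concentration 1/divergence: small divergence pins all
    populations to the base, large divergence lets them wander.
    """
    freqs = []
    for n_alleles in config.allele_count_list():
        base = rng.dirichlet(np.full(n_alleles, config.dirichlet_concentration))
        alpha = np.maximum(base / config.divergence, _MIN_ALPHA)
        pops = np.vstack([rng.dirichlet(alpha) for _ in range(config.K)])
        freqs.append(pops)
    return freqs


def _draw_fingerprints(
    config: SimulationConfig,
    rng: np.random.Generator,
    pop_freqs: list[np.ndarray],
    ancestry: np.ndarray,
) -> np.ndarray:
    """Ancestry rows x columns boolean presence matrix (pre-noise)."""
    blocks = []
    for freqs in pop_freqs:
        mixed = ancestry @ freqs  # n x A
        mixed /= mixed.sum(axis=1, keepdims=True)
        counts = rng.multinomial(config.ploidy, mixed)
        blocks.append(counts > 0)
    return np.hstack(blocks)


def _apply_noise(
    config: SimulationConfig,
    rng: np.random.Generator,
    presence: np.ndarray,
    panel: MarkerPanel,
) -> np.ndarray:
    """Scoring-error flips then block-level missingness; returns 0/1/9 scores."""
    scores = np.where(presence, PRESENT, ABSENT).astype(np.int8)
    if config.scoring_error_rate > 0:
        flips = rng.random(scores.shape) < config.scoring_error_rate
        scores[flips] = 1 - scores[flips]
    if config.missing_rate > 0:
        miss = rng.random((scores.shape[0], panel.n_markers)) < config.missing_rate
        for j, sl in enumerate(panel.marker_slices().values()):
            rows = np.flatnonzero(miss[:, j])
            if rows.size:
                scores[np.ix_(rows, range(sl.start, sl.stop))] = MISSING
    return scores


def _draw_individuals(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[MarkerPanel, list[np.ndarray], np.ndarray, np.ndarray]:
    panel = _make_panel(config)
    pop_freqs = _draw_population_frequencies(config, rng)
    ancestry = rng.dirichlet(
        np.full(config.K, config.admixture_alpha), size=config.n_individuals
    )
    fingerprints = _draw_fingerprints(config, rng, pop_freqs, ancestry)
    return panel, pop_freqs, ancestry, fingerprints


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw a structured collection; one sample per individual plus clones.

    Deterministic: identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    panel, pop_freqs, ancestry, fingerprints = _draw_individuals(config, rng)
    populations = ancestry.argmax(axis=1)

    # emission order: each individual followed by its clonal copies
    owner: list[int] = []
    is_clone: list[bool] = []
    copy_counts, copy_probs = zip(*sorted(config.clone_copy_distribution.items()))
    for i in range(config.n_individuals):
        owner.append(i)
        is_clone.append(False)
        if config.clone_rate > 0 and rng.random() < config.clone_rate:
            c = int(rng.choice(copy_counts, p=copy_probs))
            owner.extend([i] * c)
            is_clone.extend([True] * c)

    emitted = fingerprints[np.asarray(owner, dtype=int)]
    scores = _apply_noise(config, rng, emitted, panel)

    sample_ids = []
    copy_index: dict[int, int] = {}
    for ind, clone in zip(owner, is_clone):
        if clone:
            copy_index[ind] = copy_index.get(ind, 0) + 1
            sample_ids.append(f"SIM{ind + 1:05d}-C{copy_index[ind]}")
        else:
            sample_ids.append(f"SIM{ind + 1:05d}")

    matrix = AlleleMatrix(panel=panel, sample_ids=tuple(sample_ids), scores=scores)
    records = [
        AccessionRecord(
            accession_id=sid,
            name=sid,
            country=f"POP{populations[ind] + 1}",
            biological_status="landrace",
            collection="SIM",
        )
        for sid, ind in zip(sample_ids, owner)
    ]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "individual": owner,
            "population": [int(populations[i]) for i in owner],
            "clone_group": owner,
            "is_clone_copy": is_clone,
            "swapped": False,
        }
    )
    truth = GroundTruth(
        samples=samples,
        ancestry=ancestry,
        population_frequencies=pop_freqs,
        true_fingerprints=fingerprints,
    )
    return SimulationResult(matrix=matrix, records=records, truth=truth)


# ---------------------------------------------------------------------------
# paired fixture (true-to-type verification)
# ---------------------------------------------------------------------------

def make_paired_fixture(config: SimulationConfig, n_pairs: int) -> PairedFixture:
    """Emit mother-plant / in-vitro sample pairs with label swaps at rate
    ``label_swap_rate``.

    A swapped in-vitro sample carries the complete fingerprint of a different
    individual, guaranteed to differ from its owner's in at least one allele.
    """
    if n_pairs > config.n_individuals:
        raise ConfigError(
            f"n_pairs {n_pairs} exceeds n_individuals {config.n_individuals}"
        )
    rng = np.random.default_rng(config.seed)
    panel, pop_freqs, ancestry, fingerprints = _draw_individuals(config, rng)
    populations = ancestry.argmax(axis=1)

    chosen = np.arange(n_pairs)
    swap_flags = np.zeros(n_pairs, dtype=bool)
    donor = chosen.copy()
    for i in chosen:
        if rng.random() < config.label_swap_rate:
            d = _pick_swap_donor(rng, fingerprints, int(i), config.n_individuals)
            if d is not None:
                donor[i] = d
                swap_flags[i] = True

    mother = fingerprints[chosen]
    invitro = fingerprints[donor]
    emitted = np.vstack([mother, invitro])
    scores = _apply_noise(config, rng, emitted, panel)

    acc_ids = [f"SIM{i + 1:05d}" for i in chosen]
    mother_ids = [make_sample_id(acc, "mother_plant") for acc in acc_ids]
    invitro_ids = [make_sample_id(acc, "in_vitro") for acc in acc_ids]
    sample_ids = tuple(mother_ids + invitro_ids)
    matrix = AlleleMatrix(panel=panel, sample_ids=sample_ids, scores=scores)

    records = []
    for acc, ind in zip(acc_ids, chosen):
        common = dict(
            accession_id=acc,
            name=acc,
            country=f"POP{populations[ind] + 1}",
            biological_status="landrace",
            collection="SIM",
        )
        records.append(
            AccessionRecord(
                **common,
                sample_source="mother_plant",
                paired_with=make_sample_id(acc, "in_vitro"),
            )
        )
        records.append(
            AccessionRecord(
                **common,
                sample_source="in_vitro",
                paired_with=make_sample_id(acc, "mother_plant"),
            )
        )

    samples = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "individual": list(chosen) + list(donor),
            "population": [int(populations[i]) for i in chosen]
            + [int(populations[i]) for i in donor],
            "clone_group": list(chosen) + list(donor),
            "is_clone_copy": [False] * n_pairs + [True] * n_pairs,
            "swapped": [False] * n_pairs + list(swap_flags),
        }
    )
    truth = GroundTruth(
        samples=samples,
        ancestry=ancestry,
        population_frequencies=pop_freqs,
        true_fingerprints=fingerprints,
    )
    pairs = list(zip(mother_ids, invitro_ids))
    return PairedFixture(matrix=matrix, records=records, pairs=pairs, truth=truth)


def _pick_swap_donor(
    rng: np.random.Generator,
    fingerprints: np.ndarray,
    owner: int,
    n_individuals: int,
    max_tries: int = 100,
) -> Optional[int]:
    """A different individual whose fingerprint differs in >= 1 allele."""
    if n_individuals < 2:
        return None
    for _ in range(max_tries):
        d = int(rng.integers(n_individuals))
        if d != owner and (fingerprints[d] != fingerprints[owner]).any():
            return d
    candidates = [
        d
        for d in range(n_individuals)
        if d != owner and (fingerprints[d] != fingerprints[owner]).any()
    ]
    return int(rng.choice(candidates)) if candidates else None


# ---------------------------------------------------------------------------
# two-collection fixture (reconciliation)
# ---------------------------------------------------------------------------

def make_two_collection_fixture(
    config: SimulationConfig,
    n_shared: int,
    n_unique_query: int,
    n_link_errors: int,
    uniqueness_threshold: float = 0.95,
) -> TwoCollectionFixture:
    """Reference + query collections with planted link errors and uniques.

    The reference holds all ``n_individuals``; the query holds exact clones of
    the first ``n_shared`` reference individuals plus ``n_unique_query``
    individuals guaranteed below ``uniqueness_threshold`` similarity to every
    reference sample.  ``n_link_errors`` declared-transfer links are
    re-pointed to a wrong (non-identical) reference individual.
    """
    if n_shared + n_unique_query > config.n_individuals:
        raise ConfigError(
            "n_shared + n_unique_query exceeds n_individuals "
            f"({n_shared} + {n_unique_query} > {config.n_individuals})"
        )
    if n_link_errors > n_shared:
        raise ConfigError("n_link_errors cannot exceed n_shared")
    rng = np.random.default_rng(config.seed)
    panel, pop_freqs, ancestry, fingerprints = _draw_individuals(config, rng)

    ref_idx = np.arange(config.n_individuals - n_unique_query)
    unique_idx = np.arange(
        config.n_individuals - n_unique_query, config.n_individuals
    )
    shared_idx = ref_idx[:n_shared]

    # redraw query-only individuals until they clear the uniqueness margin
    ref_prints = fingerprints[ref_idx]
    unique_prints = fingerprints[unique_idx].copy()
    for row in range(unique_prints.shape[0]):
        for _ in range(200):
            sims = _presence_similarity(unique_prints[row], ref_prints)
            if sims.max(initial=0.0) < uniqueness_threshold:
                break
            anc = rng.dirichlet(np.full(config.K, config.admixture_alpha), size=1)
            unique_prints[row] = _draw_fingerprints(config, rng, pop_freqs, anc)[0]
        else:
            raise ConfigError(
                "could not draw a query-only individual below the uniqueness "
                "threshold; increase divergence or allele counts"
            )

    ref_ids = [f"REF{i + 1:05d}" for i in range(len(ref_idx))]
    reference = AlleleMatrix(
        panel=panel,
        sample_ids=tuple(ref_ids),
        scores=_apply_noise(config, rng, ref_prints, panel),
    )

    query_prints = np.vstack([fingerprints[shared_idx], unique_prints])
    query_ids = [f"QRY{i + 1:05d}" for i in range(len(query_prints))]
    query = AlleleMatrix(
        panel=panel,
        sample_ids=tuple(query_ids),
        scores=_apply_noise(config, rng, query_prints, panel),
    )

    wrong = rng.choice(n_shared, size=n_link_errors, replace=False)
    wrong_set = set(int(w) for w in wrong)
    links = []
    truth_rows = []
    for qpos in range(n_shared):
        true_ref = ref_ids[qpos]
        if qpos in wrong_set:
            target = _pick_swap_donor(rng, ref_prints, qpos, len(ref_idx))
            if target is None:
                raise ConfigError("cannot plant a link error: reference too uniform")
            linked = ref_ids[target]
        else:
            linked = true_ref
        links.append(Link(query_ids[qpos], linked, "declared_transfer"))
        truth_rows.append(
            {
                "query_id": query_ids[qpos],
                "role": "shared",
                "counterpart": true_ref,
                "link_error": qpos in wrong_set,
            }
        )
    for qpos in range(n_shared, len(query_ids)):
        truth_rows.append(
            {
                "query_id": query_ids[qpos],
                "role": "unique",
                "counterpart": None,
                "link_error": False,
            }
        )

    records = [
        AccessionRecord(
            accession_id=sid, name=sid, biological_status="landrace", collection="REF"
        )
        for sid in ref_ids
    ] + [
        AccessionRecord(
            accession_id=sid, name=sid, biological_status="landrace", collection="QRY"
        )
        for sid in query_ids
    ]
    return TwoCollectionFixture(
        reference=reference,
        query=query,
        links=links,
        records=records,
        truth=pd.DataFrame(truth_rows),
    )


def _presence_similarity(fingerprint: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Jaccard similarity of one boolean fingerprint against rows of ``others``."""
    inter = (others & fingerprint).sum(axis=1)
    union = (others | fingerprint).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = inter / union
    return np.where(union == 0, np.nan, sims)
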
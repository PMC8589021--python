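"""Core data model and I/O for dominant-scored polyploid SSR fingerprints.

Fragment presence/absence is recorded per (marker, allele) column with the
conventional ``0`` (absent), ``1`` (present) and ``9`` (missing) codes.  A
matrix row is a *sample*: either a bare accession id, or an accession id
qualified by its tissue source (``"CIP420001|mother"`` /
``"CIP420001|invitro"``) when the same accession was fingerprinted from more
than one source.

Missingness is handled at the (sample, marker) *block* level: a locus either
failed to amplify for a sample (all its allele cells are 9) or was scored in
full.  Blocks mixing 9s with scored cells are tolerated on input, reported by
:func:`validate`, and treated as missing by every downstream computation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

ABSENT = 0
PRESENT = 1
MISSING = 9

BIOLOGICAL_STATUSES = ("landrace", "breeding_line", "improved_variety", "unclassified")
SAMPLE_SOURCES = ("mother_plant", "in_vitro", "unspecified")

_SOURCE_TAGS = {"mother_plant": "mother", "in_vitro": "invitro"}
_TAG_SOURCES = {tag: src for src, tag in _SOURCE_TAGS.items()}

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to the expected delimited layout."""


class ValidationError(ValueError):
    """Data violates an AlleleMatrix / passport invariant."""


class IncompatiblePanelError(ValueError):
    """Two matrices cannot be aligned because their marker panels differ."""


class UnknownSampleError(KeyError):
    """A referenced sample id is not present in the matrix."""


# ---------------------------------------------------------------------------
# sample id convention
# ---------------------------------------------------------------------------

def make_sample_id(accession_id: str, sample_source: str = "unspecified") -> str:
    """Serialize (accession_id, sample_source) to a row id.

    ``unspecified`` sources map to the bare accession id; the two explicit
    tissue sources are appended after ``|``.
    """
    if sample_source not in SAMPLE_SOURCES:
        raise ValidationError(f"unknown sample source {sample_source!r}")
    tag = _SOURCE_TAGS.get(sample_source)
    return accession_id if tag is None else f"{accession_id}|{tag}"


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """Inverse of :func:`make_sample_id`: returns (accession_id, sample_source)."""
    if "|" in sample_id:
        acc, tag = sample_id.rsplit("|", 1)
        if tag in _TAG_SOURCES:
            return acc, _TAG_SOURCES[tag]
        raise ValidationError(f"unknown sample source tag {tag!r} in {sample_id!r}")
    return sample_id, "unspecified"


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """One SSR locus: its name, scored allele labels and optional metadata."""

    name: str
    allele_labels: tuple[str, ...]
    motif: str = ""
    size_range_bp: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("marker name must be non-empty")
        if len(self.allele_labels) == 0:
            raise ValidationError(f"marker {self.name!r} has no allele labels")
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValidationError(f"marker {self.name!r} has duplicate allele labels")
        if self.size_range_bp is not None:
            low, high = self.size_range_bp
            if low > high:
                raise ValidationError(
                    f"marker {self.name!r}: size range low {low} > high {high}"
                )

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of markers defining the matrix column blocks."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        names = [mk.name for mk in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate marker names in panel: {dupes}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(mk.name for mk in self.markers)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_columns(self) -> int:
        return sum(mk.n_alleles for mk in self.markers)

    @property
    def column_labels(self) -> tuple[str, ...]:
        return tuple(
            f"{mk.name}_{allele}" for mk in self.markers for allele in mk.allele_labels
        )

    def marker_index(self, name: str) -> int:
        for i, mk in enumerate(self.markers):
            if mk.name == name:
                return i
        raise KeyError(f"marker {name!r} not in panel")

    def marker_slice(self, name: str) -> slice:
        """Column slice of the marker's allele block."""
        start = 0
        for mk in self.markers:
            if mk.name == name:
                return slice(start, start + mk.n_alleles)
            start += mk.n_alleles
        raise KeyError(f"marker {name!r} not in panel")

    def marker_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        for mk in self.markers:
            out[mk.name] = slice(start, start + mk.n_alleles)
            start += mk.n_alleles
        return out

    @classmethod
    def from_column_labels(cls, labels: Sequence[str]) -> "MarkerPanel":
        """Infer a panel from ``<marker>_<allele>`` column headers.

        Columns of a marker must be contiguous; allele size ranges are
        inferred when all allele labels are integers.
        """
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        last: Optional[str] = None
        for label in labels:
            if "_" not in label:
                raise FormatError(
                    f"column {label!r} is not of the form <marker>_<allele>"
                )
            marker, allele = label.rsplit("_", 1)
            if marker not in groups:
                groups[marker] = []
                order.append(marker)
            elif marker != last:
                raise FormatError(f"columns for marker {marker!r} are not contiguous")
            groups[marker].append(allele)
            last = marker
        markers = []
        for name in order:
            alleles = groups[name]
            size_range = None
            if all(a.isdigit() for a in alleles):
                sizes = [int(a) for a in alleles]
                size_range = (min(sizes), max(sizes))
            markers.append(
                Marker(name=name, allele_labels=tuple(alleles), size_range_bp=size_range)
            )
        return cls(markers=tuple(markers))


# ---------------------------------------------------------------------------
# allele matrix
# ---------------------------------------------------------------------------

@dataclass
class AlleleMatrix:
    """Samples x (marker, allele) grid of dominant scores.

    ``scores`` is an int8 array over {0, 1, 9} with one row per sample and
    columns in panel order.
    """

    panel: MarkerPanel
    sample_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        scores = np.asarray(self.scores, dtype=np.int8)
        if scores.ndim != 2:
            raise ValidationError("scores must be a 2-D array")
        if scores.shape != (len(self.sample_ids), self.panel.n_columns):
            raise ValidationError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.panel.n_columns} columns"
            )
        bad = ~np.isin(scores, (ABSENT, PRESENT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid score {int(scores[i, j])} at sample "
                f"{self.sample_ids[int(i)]!r}, column "
                f"{self.panel.column_labels[int(j)]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dupes = sorted({s for s in self.sample_ids if s in seen or seen.add(s)})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        self.scores = scores

    # -- basic shape ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.panel.n_markers

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise UnknownSampleError(sample_id) from None

    # -- block-level missingness --------------------------------------------

    def block_scored(self) -> np.ndarray:
        """Boolean (n_samples, n_markers): True where the locus block holds no 9s.

        Blocks mixing missing and scored cells count as *not* scored (the
        conservative downstream convention).
        """
        out = np.empty((self.n_samples, self.n_markers), dtype=bool)
        for j, sl in enumerate(self.panel.marker_slices().values()):
            out[:, j] = ~(self.scores[:, sl] == MISSING).any(axis=1)
        return out

    def column_scored(self) -> np.ndarray:
        """Boolean (n_samples, n_columns) expansion of :meth:`block_scored`."""
        blocks = self.block_scored()
        reps = [mk.n_alleles for mk in self.panel.markers]
        return np.repeat(blocks, reps, axis=1)

    def marker_block(self, name: str) -> np.ndarray:
        return self.scores[:, self.panel.marker_slice(name)]

    def presence(self) -> np.ndarray:
        """Boolean presence calls; missing cells read as False."""
        return self.scores == PRESENT

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleMatrix):
            return NotImplemented
        return (
            self.panel == other.panel
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.scores, other.scores)
        )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_matrix(path: PathLike, panel: Optional[MarkerPanel] = None) -> AlleleMatrix:
    """Read a 0/1/9 genotype table (CSV, first column sample id).

    When ``panel`` is given the header must match its column labels exactly;
    otherwise the panel is inferred from the header.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 1:
        raise FormatError(f"{path}: header row is empty")
    labels = header[1:]
    if panel is None:
        panel = MarkerPanel.from_column_labels(labels)
    elif tuple(labels) != panel.column_labels:
        raise IncompatiblePanelError(
            f"{path}: header columns do not match the supplied panel"
        )

    ids: list[str] = []
    seen: set[str] = set()
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
        sid = row[0]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample id {sid!r} (line {lineno})")
        seen.add(sid)
        ids.append(sid)

    if ids:
        raw = np.array([row[1:] for row in rows[1:]], dtype=object)
        valid = np.isin(raw, ("0", "1", "9"))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise FormatError(
                f"{path}: invalid cell {raw[i, j]!r} at sample {ids[int(i)]!r}, "
                f"column {labels[int(j)]!r}"
            )
        scores = raw.astype(np.int8)
    else:
        scores = np.empty((0, panel.n_columns), dtype=np.int8)
    return AlleleMatrix(panel=panel, sample_ids=tuple(ids), scores=scores)


def write_matrix(m: AlleleMatrix, path: PathLike) -> None:
    """Write the canonical delimited form (CSV, cells 0/1/9, panel column order)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession_id", *m.panel.column_labels])
        for sid, row in zip(m.sample_ids, m.scores):
            writer.writerow([sid, *(str(int(v)) for v in row)])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Non-throwing report of data-quality issues in an AlleleMatrix."""

    mixed_blocks: list[tuple[str, str]] = field(default_factory=list)
    monomorphic_markers: list[str] = field(default_factory=list)
    all_missing_samples: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.mixed_blocks or self.monomorphic_markers or self.all_missing_samples
        )


def validate(m: AlleleMatrix) -> ValidationReport:
    """Report mixed missing/scored blocks, monomorphic markers and empty samples.

    Pure: never mutates or raises on data-quality findings.
    """
    report = ValidationReport()
    slices = m.panel.marker_slices()
    for name, sl in slices.items():
        block = m.scores[:, sl]
        missing = block == MISSING
        mixed = missing.any(axis=1) & ~missing.all(axis=1)
        for i in np.flatnonzero(mixed):
            report.mixed_blocks.append((m.sample_ids[int(i)], name))
        scored = ~missing.any(axis=1)
        if scored.any():
            sub = block[scored]
            if (sub == sub[0]).all():
                report.monomorphic_markers.append(name)
    if m.n_samples:
        all_missing = (m.scores == MISSING).all(axis=1)
        report.all_missing_samples = [
            m.sample_ids[int(i)] for i in np.flatnonzero(all_missing)
        ]
    return report


# ---------------------------------------------------------------------------
# subsetting and merging
# ---------------------------------------------------------------------------

def subset(m: AlleleMatrix, ids: Sequence[str]) -> AlleleMatrix:
    """Restrict rows to ``ids`` (in the given order); panel unchanged."""
    index = {sid: i for i, sid in enumerate(m.sample_ids)}
    rows = []
    for sid in ids:
        if sid not in index:
            raise UnknownSampleError(sid)
        rows.append(index[sid])
    if rows:
        scores = m.scores[np.asarray(rows, dtype=int)]
    else:
        scores = np.empty((0, m.panel.n_columns), dtype=np.int8)
    return AlleleMatrix(panel=m.panel, sample_ids=tuple(ids), scores=scores)


def _union_panel(a: MarkerPanel, b: MarkerPanel) -> MarkerPanel:
    if set(a.marker_names) != set(b.marker_names):
        only_a = sorted(set(a.marker_names) - set(b.marker_names))
        only_b = sorted(set(b.marker_names) - set(a.marker_names))
        raise IncompatiblePanelError(
            f"marker name sets differ (only in first: {only_a}; only in second: {only_b})"
        )
    markers = []
    for mk in a.markers:
        other = b.markers[b.marker_index(mk.name)]
        extra = [al for al in other.allele_labels if al not in mk.allele_labels]
        labels = tuple(mk.allele_labels) + tuple(extra)
        size_range = mk.size_range_bp
        if all(al.isdigit() for al in labels):
            sizes = [int(al) for al in labels]
            size_range = (min(sizes), max(sizes))
        markers.append(
            Marker(
                name=mk.name,
                allele_labels=labels,
                motif=mk.motif or other.motif,
                size_range_bp=size_range,
            )
        )
    return MarkerPanel(markers=tuple(markers))


def _project(m: AlleleMatrix, target: MarkerPanel) -> AlleleMatrix:
    """Re-express ``m`` on a superset panel.

    Alleles unknown to ``m``'s panel are scored absent for samples whose block
    was scored and missing otherwise (a scored locus is positive evidence that
    unobserved fragments were not present; a failed locus says nothing).
    """
    scores = np.empty((m.n_samples, target.n_columns), dtype=np.int8)
    blocks = m.block_scored()
    tgt_slices = target.marker_slices()
    for j, mk in enumerate(m.panel.markers):
        tgt_mk = target.markers[target.marker_index(mk.name)]
        tsl = tgt_slices[mk.name]
        block = np.where(blocks[:, j : j + 1], ABSENT, MISSING).astype(np.int8)
        block = np.repeat(block, tgt_mk.n_alleles, axis=1)
        src = m.marker_block(mk.name)
        pos = [tgt_mk.allele_labels.index(al) for al in mk.allele_labels]
        block[:, pos] = src
        scores[:, tsl] = block
    return AlleleMatrix(panel=target, sample_ids=m.sample_ids, scores=scores)


def align_panels(a: AlleleMatrix, b: AlleleMatrix) -> tuple[AlleleMatrix, AlleleMatrix]:
    """Re-express two matrices on their union panel (marker order follows ``a``)."""
    union = _union_panel(a.panel, b.panel)
    return _project(a, union), _project(b, union)


def merge(
    a: AlleleMatrix,
    b: AlleleMatrix,
    collections: tuple[str, str] = ("a", "b"),
) -> AlleleMatrix:
    """Row-wise union of two matrices over the union of their allele labels.

    Sample ids occurring in both inputs are qualified as
    ``"<collection>:<id>"`` using ``collections``.
    """
    aa, bb = align_panels(a, b)
    colliding = set(aa.sample_ids) & set(bb.sample_ids)
    ids_a = tuple(
        f"{collections[0]}:{sid}" if sid in colliding else sid for sid in aa.sample_ids
    )
    ids_b = tuple(
        f"{collections[1]}:{sid}" if sid in colliding else sid for sid in bb.sample_ids
    )
    scores = np.vstack([aa.scores, bb.scores]) if (aa.n_samples or bb.n_samples) else (
        np.empty((0, aa.panel.n_columns), dtype=np.int8)
    )
    return AlleleMatrix(panel=aa.panel, sample_ids=ids_a + ids_b, scores=scores)


# ---------------------------------------------------------------------------
# passport metadata
# ---------------------------------------------------------------------------

@dataclass
class AccessionRecord:
    """Passport metadata for one sample of one accession."""

    accession_id: str
    name: str = ""
    country: str = ""
    biological_status: str = "unclassified"
    collection: str = ""
    sample_source: str = "unspecified"
    paired_with: Optional[str] = None

    def __post_init__(self) -> None:
        if self.biological_status not in BIOLOGICAL_STATUSES:
            raise ValidationError(
                f"{self.accession_id}: biological_status must be one of "
                f"{BIOLOGICAL_STATUSES}, got {self.biological_status!r}"
            )
        if self.sample_source not in SAMPLE_SOURCES:
            raise ValidationError(
                f"{self.accession_id}: sample_source must be one of "
                f"{SAMPLE_SOURCES}, got {self.sample_source!r}"
            )

    @property
    def sample_id(self) -> str:
        return make_sample_id(self.accession_id, self.sample_source)


_PASSPORT_FIELDS = (
    "accession_id",
    "name",
    "country",
    "biological_status",
    "collection",
    "sample_source",
    "paired_with",
)


def read_passport(path: PathLike) -> list[AccessionRecord]:
    """Read the delimited passport table (one row per sample)."""
    path = Path(path)
    records: list[AccessionRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "accession_id" not in reader.fieldnames:
            raise FormatError(f"{path}: passport table must have an accession_id column")
        for row in reader:
            kwargs = {k: row.get(k, "") or "" for k in _PASSPORT_FIELDS}
            if not kwargs["biological_status"]:
                kwargs["biological_status"] = "unclassified"
            if not kwargs["sample_source"]:
                kwargs["sample_source"] = "unspecified"
            kwargs["paired_with"] = kwargs["paired_with"] or None
            records.append(AccessionRecord(**kwargs))
    _check_pairings(records)
    return records


def write_passport(records: Iterable[AccessionRecord], path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PASSPORT_FIELDS)
        for rec in records:
            writer.writerow(
                [
                    rec.accession_id,
                    rec.name,
                    rec.country,
                    rec.biological_status,
                    rec.collection,
                    rec.sample_source,
                    rec.paired_with or "",
                ]
            )


def _check_pairings(records: Sequence[AccessionRecord]) -> None:
    by_sample = {rec.sample_id: rec for rec in records}
    for rec in records:
        if rec.paired_with is None:
            continue
        other = by_sample.get(rec.paired_with)
        if other is None:
            raise ValidationError(
                f"{rec.sample_id}: paired_with references unknown sample "
                f"{rec.paired_with!r}"
            )
        if other.accession_id != rec.accession_id:
            raise ValidationError(
                f"{rec.sample_id}: paired sample {rec.paired_with!r} belongs to a "
                "different accession"
            )
        if other.sample_source == rec.sample_source:
            raise ValidationError(
                f"{rec.sample_id}: paired sample {rec.paired_with!r} has the same "
                "sample source"
            )


def groups_from_passport(
    records: Sequence[AccessionRecord], by: str
) -> dict[str, str]:
    """Map sample ids to a grouping variable (e.g. country, biological_status)."""
    if by not in ("country", "biological_status", "collection"):
        raise ValueError(f"cannot group by {by!r}")
    return {rec.sample_id: getattr(rec, by) for rec in records}
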
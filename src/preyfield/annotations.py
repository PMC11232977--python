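"""Object-level annotation tables and dive/strike event tables.

One :class:`ObjectRecord` describes one imaged object (typically a krill)
in one video frame: its apparent length in pixels, the analyst's binary
resolvability call, and an optional subtype qualifying how the animal
presented (bent, partially out of frame, axial/head-on, motion-blurred,
or part of a tightly packed aggregation).

Two CSV dialects are supported:

``simple_csv``
    Header ``image_id,object_id,imaged_length_px,resolvability,subtype``
    with an optional trailing ``timestamp_s`` column.

``viame_csv``
    The detection CSV exported by the VIAME annotation toolkit.  Columns:
    track id, image/video identifier, frame id, bounding box
    ``TL_x, TL_y, BR_x, BR_y``, detection confidence, target length, then
    repeated (class label, score) pairs.  Lines starting with ``#`` are
    comments.  The imaged length is the explicit target-length column when
    positive, otherwise the bounding-box diagonal — the best single-box
    proxy for an elongated target's projected length.  Class labels encode
    resolvability and subtype as ``resolvable``, ``unresolvable`` or
    ``resolvable_<subtype>`` (e.g. ``resolvable_bent``).

Two distinct filters are exposed and must not be conflated:

* :func:`boundary_fit_subset` — records usable for *size*-based work
  (logistic boundary fitting, length histograms): excludes ``partial``
  and ``packed_aggregation`` subtypes whose pixel lengths are unreliable.
* :func:`countable_per_image` — records usable for *counting*: every
  record labelled resolvable, of any subtype, counts toward density.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

RESOLVABLE = "resolvable"
UNRESOLVABLE = "unresolvable"
RESOLVABILITY_CLASSES = frozenset({RESOLVABLE, UNRESOLVABLE})

SUBTYPES = frozenset(
    {"plain", "bent", "partial", "axial", "motion_blurred", "packed_aggregation", "none"}
)
#: subtypes whose pixel lengths are untrustworthy for size-based fitting
SIZE_EXCLUDED_SUBTYPES = frozenset({"partial", "packed_aggregation"})
#: subtypes an unresolvable object may carry (featureless blobs have no presentation)
UNRESOLVABLE_SUBTYPES = frozenset({"plain", "none"})

SIMPLE_COLUMNS = ["image_id", "object_id", "imaged_length_px", "resolvability", "subtype"]

EVENT_KINDS = frozenset({"dive_start", "dive_end", "strike"})


@dataclass(frozen=True)
class ObjectRecord:
    """A single annotated object in a single image."""

    image_id: str
    object_id: str
    imaged_length_px: float
    resolvability: str
    subtype: str = "plain"
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        if not self.imaged_length_px > 0:
            raise ValidationError(
                f"imaged_length_px must be > 0, got {self.imaged_length_px!r} "
                f"(object {self.object_id!r} in image {self.image_id!r})"
            )
        if self.resolvability not in RESOLVABILITY_CLASSES:
            raise ValidationError(
                f"unknown resolvability {self.resolvability!r} "
                f"(object {self.object_id!r}); expected one of {sorted(RESOLVABILITY_CLASSES)}"
            )
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"unknown subtype {self.subtype!r} (object {self.object_id!r}); "
                f"expected one of {sorted(SUBTYPES)}"
            )
        if self.resolvability == UNRESOLVABLE and self.subtype not in UNRESOLVABLE_SUBTYPES:
            raise ValidationError(
                f"unresolvable object {self.object_id!r} may not carry subtype "
                f"{self.subtype!r}; featureless objects have no presentation subtype"
            )


@dataclass(frozen=True)
class AnnotationSet:
    """An immutable collection of object records grouped by image."""

    records: tuple[ObjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def n_images(self) -> int:
        return len({r.image_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per record."""
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "object_id": [r.object_id for r in self.records],
                "imaged_length_px": [r.imaged_length_px for r in self.records],
                "resolvability": [r.resolvability for r in self.records],
                "subtype": [r.subtype for r in self.records],
                "timestamp_s": [r.timestamp_s for r in self.records],
            }
        )


@dataclass(frozen=True)
class DiveEvent:
    """A timestamped dive-log event (dive start/end or a feeding strike)."""

    time_s: float
    depth_m: float
    kind: str

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValidationError(f"depth_m must be >= 0, got {self.depth_m}")
        if self.kind not in EVENT_KINDS:
            raise ValidationError(
                f"unknown event kind {self.kind!r}; expected one of {sorted(EVENT_KINDS)}"
            )


def _record_from_simple_row(row: dict, rownum: int) -> ObjectRecord:
    try:
        length = float(row["imaged_length_px"])
    except (TypeError, ValueError):
        raise FormatError(
            f"row {rownum}: imaged_length_px {row.get('imaged_length_px')!r} is not a number"
        ) from None
    ts = row.get("timestamp_s")
    try:
        return ObjectRecord(
            image_id=str(row["image_id"]),
            object_id=str(row["object_id"]),
            imaged_length_px=length,
            resolvability=str(row["resolvability"]).strip().lower(),
            subtype=str(row["subtype"]).strip().lower() or "plain",
            timestamp_s=float(ts) if ts not in (None, "") else None,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {rownum}: {exc}") from None


def _parse_viame_label(label: str, rownum: int) -> tuple[str, str]:
    lab = label.strip().lower()
    if lab in (UNRESOLVABLE, "unresolvable_plain"):
        return UNRESOLVABLE, "plain"
    if lab in (RESOLVABLE, "krill", "resolvable_plain"):
        return RESOLVABLE, "plain"
    if lab.startswith("resolvable_"):
        subtype = lab[len("resolvable_"):]
        if subtype in SUBTYPES:
            return RESOLVABLE, subtype
    raise FormatError(f"row {rownum}: unrecognised VIAME class label {label!r}")


def _read_viame(path: Path) -> list[ObjectRecord]:
    records: list[ObjectRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 11:
                raise FormatError(
                    f"row {rownum}: VIAME detection rows need >= 11 columns, got {len(row)}"
                )
            try:
                tlx, tly, brx, bry = (float(v) for v in row[3:7])
                target_length = float(row[8])
            except ValueError:
                raise FormatError(f"row {rownum}: non-numeric bounding box or length") from None
            length = target_length if target_length > 0 else math.hypot(brx - tlx, bry - tly)
            resolvability, subtype = _parse_viame_label(row[9], rownum)
            try:
                records.append(
                    ObjectRecord(
                        image_id=str(row[1]),
                        object_id=str(row[0]),
                        imaged_length_px=length,
                        resolvability=resolvability,
                        subtype=subtype,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
    return records


def read_annotations(path: str | Path, dialect: str = "simple_csv") -> AnnotationSet:
    """Read and validate an object-annotation table.

    Parameters
    ----------
    path
        CSV file in one of the two supported dialects.
    dialect
        ``"simple_csv"`` or ``"viame_csv"`` (see module docstring).

    Raises
    ------
    FormatError
        Missing required columns or unparseable cells, citing the row.
    ValidationError
        Well-formed rows violating record invariants, citing the row.
    """
    path = Path(path)
    if dialect == "viame_csv":
        return AnnotationSet(tuple(_read_viame(path)))
    if dialect != "simple_csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in SIMPLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        records = [
            _record_from_simple_row(row, rownum)
            for rownum, row in enumerate(reader, start=2)
        ]
    return AnnotationSet(tuple(records))


def write_annotations(path: str | Path, annotations: AnnotationSet) -> None:
    """Write an annotation set in the ``simple_csv`` dialect (lossless round trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIMPLE_COLUMNS + ["timestamp_s"])
        for r in annotations:
            writer.writerow(
                [
                    r.image_id,
                    r.object_id,
                    repr(r.imaged_length_px),
                    r.resolvability,
                    r.subtype,
                    "" if r.timestamp_s is None else repr(r.timestamp_s),
                ]
            )


def boundary_fit_subset(annotations: AnnotationSet) -> list[tuple[float, int]]:
    """Size/class pairs usable for boundary fitting.

    Excludes ``partial`` (clipped by the frame edge) and
    ``packed_aggregation`` (not individually delineated) records, whose
    pixel lengths do not reflect a single animal's projected length.

    Returns
    -------
    list of ``(imaged_length_px, is_resolvable)`` with resolvable coded 1,
    in stable input order.
    """
    if len(annotations) == 0:
        raise ValidationError("cannot build a boundary-fit subset from an empty annotation set")
    pairs = [
        (r.imaged_length_px, 1 if r.resolvability == RESOLVABLE else 0)
        for r in annotations
        if r.subtype not in SIZE_EXCLUDED_SUBTYPES
    ]
    if not pairs:
        raise ValidationError(
            "all records were excluded (partial / packed_aggregation); nothing to fit"
        )
    return pairs


def countable_per_image(annotations: AnnotationSet) -> pd.DataFrame:
    """Per-image counts of countable (resolvable-class) objects.

    Every record labelled resolvable counts, whatever its subtype: a bent,
    partial, axial or motion-blurred krill is still a krill inside the
    imaged volume.  Images whose records are all unresolvable appear with
    count 0.

    Returns
    -------
    DataFrame with columns ``image_id`` and ``count``, one row per
    distinct image, in first-appearance order.
    """
    if len(annotations) == 0:
        raise ValidationError("cannot count objects in an empty annotation set")
    counts: Counter[str] = Counter()
    order: list[str] = []
    seen: set[str] = set()
    for r in annotations:
        if r.image_id not in seen:
            seen.add(r.image_id)
            order.append(r.image_id)
            counts[r.image_id] = 0
        if r.resolvability == RESOLVABLE:
            counts[r.image_id] += 1
    return pd.DataFrame({"image_id": order, "count": [counts[i] for i in order]})


def read_dive_events(path: str | Path) -> list[DiveEvent]:
    """Read a ``time_s,depth_m,kind`` CSV of dive/strike events, sorted by time."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"time_s", "depth_m", "kind"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected header time_s,depth_m,kind")
        events = []
        for rownum, row in enumerate(reader, start=2):
            try:
                events.append(
                    DiveEvent(float(row["time_s"]), float(row["depth_m"]), row["kind"].strip())
                )
            except ValueError:
                raise FormatError(f"row {rownum}: non-numeric time or depth") from None
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
    return sorted(events, key=lambda e: e.time_s)
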
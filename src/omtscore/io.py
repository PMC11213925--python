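"""Readers, writers and data model for segmentation outputs and cohort metadata.

Coordinate convention: 0-based pixel coordinates at 0.50 microns per pixel
(mpp), origin at the top-left, x rightward, y downward.  Layer masks are
single-channel 8-bit label images with the fixed codebook

====  =============
code  tissue layer
====  =============
0     background
1     other tissue (connective etc.)
2     basal layer
3     epithelial layer
4     keratin layer
====  =============

Nuclei are stored as a JSON object ``{"mpp": float, "nuclei": [...]}`` where
each entry carries an integer id, a centroid, a closed contour polygon and a
class in ``{basal_epithelial, epithelial, other}``.  Cohort metadata is a flat
CSV, one row per slide.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Point, Polygon

DEFAULT_MPP = 0.50

LAYER_BACKGROUND = 0
LAYER_OTHER_TISSUE = 1
LAYER_BASAL = 2
LAYER_EPITHELIUM = 3
LAYER_KERATIN = 4
VALID_LAYER_CODES = frozenset({0, 1, 2, 3, 4})

#: layer codes counted as epithelium when filtering tiles
EPITHELIUM_CODES = (LAYER_BASAL, LAYER_EPITHELIUM, LAYER_KERATIN)


class NucleusClass(str, Enum):
    """The three classes emitted by the upstream nuclear segmentation model."""

    BASAL_EPITHELIAL = "basal_epithelial"
    EPITHELIAL = "epithelial"
    OTHER = "other"


class WHOGrade(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class BinaryGrade(str, Enum):
    LOW_RISK = "low_risk"
    HIGH_RISK = "high_risk"


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus: centroid, contour polygon and class label."""

    nucleus_id: int
    centroid: tuple[float, float]
    contour: tuple[tuple[float, float], ...]
    model_class: NucleusClass

    def validate(self) -> None:
        if len(self.contour) < 3:
            raise ValueError(
                f"nucleus {self.nucleus_id}: contour needs >=3 vertices"
            )
        arr = np.asarray(self.contour, dtype=float)
        if (arr < 0).any() or min(self.centroid) < 0:
            raise ValueError(f"nucleus {self.nucleus_id}: negative coordinates")
        poly = Polygon(self.contour)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                f"nucleus {self.nucleus_id}: contour must be a simple polygon "
                "with positive area"
            )
        hull = poly.convex_hull
        if not hull.buffer(1e-9).contains(Point(self.centroid)):
            raise ValueError(
                f"nucleus {self.nucleus_id}: centroid outside contour hull"
            )


@dataclass
class LayerMask:
    """Integer label image of tissue layers plus its physical resolution."""

    labels: np.ndarray
    resolution_mpp: float = DEFAULT_MPP

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or 0 in self.labels.shape:
            raise ValueError("layer mask must be a non-empty 2-D grid")
        if self.resolution_mpp <= 0:
            raise ValueError("resolution_mpp must be > 0")
        bad = {int(v) for v in np.unique(self.labels)} - VALID_LAYER_CODES
        if bad:
            raise ValueError(f"invalid layer codes present: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # (rows, cols) = (height, width)


@dataclass(frozen=True)
class SlideRecord:
    slide_id: str
    patient_id: str
    transformed: int
    time_to_event: float
    who_grade: WHOGrade
    binary_grade: BinaryGrade
    age: float
    sex: int
    site: int

    def validate(self) -> None:
        if self.transformed not in (0, 1):
            raise ValueError(f"{self.slide_id}: transformed must be 0/1")
        if self.time_to_event < 0:
            raise ValueError(f"{self.slide_id}: negative time_to_event")
        if not self.patient_id:
            raise ValueError(f"{self.slide_id}: empty patient_id")


@dataclass
class CohortTable:
    """Ordered collection of slide records with unique slide ids."""

    slides: list[SlideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.slide_id for s in self.slides]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate slide_id(s): {sorted(dupes)}")
        for s in self.slides:
            s.validate()

    def __len__(self) -> int:
        return len(self.slides)

    def __iter__(self):
        return iter(self.slides)

    @property
    def slide_ids(self) -> list[str]:
        return [s.slide_id for s in self.slides]

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.slides]

    def labels(self) -> np.ndarray:
        return np.array([s.transformed for s in self.slides], dtype=int)


# ---------------------------------------------------------------------------
# nuclei JSON


def read_nuclei(path: str | Path) -> list[NucleusRecord]:
    """Read a nuclei JSON file into a list of validated records.

    Order is preserved; every entry yields exactly one record or an error.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict) or "nuclei" not in payload:
        raise ValueError(f"{path}: expected object with a 'nuclei' list")
    records: list[NucleusRecord] = []
    for i, entry in enumerate(payload["nuclei"]):
        try:
            cls = NucleusClass(entry["class"])
        except ValueError as exc:
            raise ValueError(
                f"{path}: entry {i}: unknown nucleus class {entry.get('class')!r}"
            ) from exc
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: entry {i}: malformed nucleus entry") from exc
        rec = NucleusRecord(
            nucleus_id=int(entry["id"]),
            centroid=(float(entry["centroid"][0]), float(entry["centroid"][1])),
            contour=tuple((float(x), float(y)) for x, y in entry["contour"]),
            model_class=cls,
        )
        rec.validate()
        records.append(rec)
    return records


def write_nuclei(
    path: str | Path, nuclei: Iterable[NucleusRecord], mpp: float = DEFAULT_MPP
) -> None:
    payload = {
        "mpp": mpp,
        "nuclei": [
            {
                "id": n.nucleus_id,
                "centroid": list(n.centroid),
                "contour": [list(v) for v in n.contour],
                "class": n.model_class.value,
            }
            for n in nuclei
        ],
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# layer masks (PNG + sidecar JSON)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_layer_mask(path: str | Path) -> LayerMask:
    """Read a single-channel PNG label image plus its mpp sidecar."""
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    mpp = DEFAULT_MPP
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        mpp = float(json.loads(sidecar.read_text())["mpp"])
    return LayerMask(labels=arr.astype(np.uint8), resolution_mpp=mpp)


def write_layer_mask(path: str | Path, mask: LayerMask) -> None:
    path = Path(path)
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
    _sidecar_path(path).write_text(json.dumps({"mpp": mask.resolution_mpp}))


# ---------------------------------------------------------------------------
# cohort CSV

COHORT_COLUMNS = [
    "slide_id",
    "patient_id",
    "transformed",
    "time_to_event_years",
    "who_grade",
    "binary_grade",
    "age",
    "sex",
    "site",
]


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV (see :data:`COHORT_COLUMNS`)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        slides = [
            SlideRecord(
                slide_id=row["slide_id"],
                patient_id=row["patient_id"],
                transformed=int(row["transformed"]),
                time_to_event=float(row["time_to_event_years"]),
                who_grade=WHOGrade(row["who_grade"]),
                binary_grade=BinaryGrade(row["binary_grade"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                site=int(row["site"]),
            )
            for row in reader
        ]
    return CohortTable(slides=slides)


def write_cohort(path: str | Path, cohort: CohortTable) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for s in cohort:
            writer.writerow(
                [
                    s.slide_id,
                    s.patient_id,
                    s.transformed,
                    repr(s.time_to_event),
                    s.who_grade.value,
                    s.binary_grade.value,
                    repr(s.age),
                    s.sex,
                    s.site,
                ]
            )


def cohort_to_frame(cohort: CohortTable):
    """Cohort as a pandas DataFrame (one row per slide)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "slide_id": s.slide_id,
                "patient_id": s.patient_id,
                "transformed": s.transformed,
                "time_to_event_years": s.time_to_event,
                "who_grade": s.who_grade.value,
                "binary_grade": s.binary_grade.value,
                "age": s.age,
                "sex": s.sex,
                "site": s.site,
            }
            for s in cohort
        ]
    )
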
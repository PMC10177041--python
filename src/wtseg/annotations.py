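"""Polygon annotations: XML I/O, rasterization and case-exclusive splits.

Annotations are simple polygons in base-resolution pixel coordinates
attached to a case.  The on-disk dialect mirrors the ASAP annotation
format: ``ASAP_Annotations`` → ``Annotations`` → repeated ``Annotation``
elements whose ``PartOfGroup`` attribute carries the tissue-class name,
each holding ``Coordinates``/``Coordinate`` children with ``Order``,
``X`` and ``Y``.  Images travel as plain rasters (PNG/TIFF) with the
pixel spacing recorded in a sidecar JSON, never as proprietary WSI
containers.

Coordinate convention: 0-based pixel indices with x = column and
y = row; the center of pixel (row r, col c) sits at (c + 0.5, r + 0.5).
A pixel belongs to a polygon iff its center does (half-open coverage),
so an axis-aligned square with corners (10,10)–(20,20) covers exactly
the pixel block [10,20)×[10,20).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from lxml import etree
from shapely.geometry import Polygon

from .taxonomy import UNANNOTATED, ClassTaxonomy

__all__ = [
    "PolygonAnnotation",
    "CaseRecord",
    "AnnotationSet",
    "SplitSpec",
    "LabeledImage",
    "read_annotations",
    "write_annotations",
    "split_by_case",
    "rasterize",
]

logger = logging.getLogger(__name__)


@dataclass
class PolygonAnnotation:
    case_id: str
    class_id: int
    vertices: list[tuple[float, float]]  # (x, y) at base resolution
    annotation_id: int

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class CaseRecord:
    case_id: str
    image_path: str | None = None
    spacing: float = 0.24  # μm/pixel at base resolution

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("base pixel spacing must be positive")


@dataclass
class AnnotationSet:
    annotations: list[PolygonAnnotation]
    cases: list[CaseRecord]

    def __post_init__(self) -> None:
        known = {c.case_id for c in self.cases}
        for a in self.annotations:
            if a.case_id not in known:
                raise ValueError(f"annotation references unknown case {a.case_id!r}")

    def case(self, case_id: str) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(f"unknown case id: {case_id!r}")

    def for_case(self, case_id: str) -> list[PolygonAnnotation]:
        self.case(case_id)
        return [a for a in self.annotations if a.case_id == case_id]


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]  # case id -> train | validation | test

    PARTITIONS = ("train", "validation", "test")

    def cases_in(self, partition: str) -> list[str]:
        return [c for c, p in self.assignment.items() if p == partition]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.assignment, indent=2))


# ---------------------------------------------------------------------------
# XML I/O


def write_annotations(path: str | Path, annotations: list[PolygonAnnotation],
                      taxonomy: ClassTaxonomy) -> None:
    """Write one case's polygons in the ASAP-style XML dialect."""
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    id_to_name = {c.id: c.name for c in taxonomy.classes}
    for a in annotations:
        el = etree.SubElement(
            anns,
            "Annotation",
            Name=f"Annotation {a.annotation_id}",
            Type="Polygon",
            PartOfGroup=id_to_name[a.class_id],
        )
        coords = etree.SubElement(el, "Coordinates")
        for order, (x, y) in enumerate(a.vertices):
            etree.SubElement(
                coords, "Coordinate", Order=str(order), X=repr(float(x)),
                Y=repr(float(y)),
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def _parse_case_xml(path: Path, case_id: str, taxonomy: ClassTaxonomy,
                    start_id: int) -> tuple[list[PolygonAnnotation], int]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed annotation XML {path}: {e}") from e
    out: list[PolygonAnnotation] = []
    dropped = 0
    unknown: list[str] = []
    next_id = start_id
    for el in tree.findall(".//Annotation"):
        cls_name = el.get("PartOfGroup", "")
        if taxonomy.is_known_excluded(cls_name):
            dropped += 1
            continue
        try:
            cls = taxonomy.class_of(cls_name)
        except KeyError:
            unknown.append(cls_name)
            continue
        coords = sorted(
            el.findall(".//Coordinate"), key=lambda c: int(c.get("Order", "0"))
        )
        verts = [(float(c.get("X")), float(c.get("Y"))) for c in coords]
        # honor an id encoded in the Name ("Annotation 17"), else number
        # sequentially in document order
        name = el.get("Name", "")
        ann_id = next_id
        if name.rsplit(" ", 1)[-1].isdigit():
            ann_id = int(name.rsplit(" ", 1)[-1])
        out.append(PolygonAnnotation(case_id, cls, verts, ann_id))
        next_id = max(next_id, ann_id) + 1
    if unknown:
        raise ValueError(
            f"{path}: unknown tissue class name(s): {sorted(set(unknown))}"
        )
    if dropped:
        logger.info("%s: dropped %d annotation(s) of excluded classes", path, dropped)
    return out, next_id


def read_annotations(path: str | Path, taxonomy: ClassTaxonomy) -> AnnotationSet:
    """Read annotations for a cohort directory or a single case XML.

    A cohort directory must hold a ``manifest.json`` listing cases with
    their XML/image paths and base spacing.  A bare ``.xml`` path is read
    as a single anonymous case.  Annotations of excluded classes are
    dropped (count logged); unknown class names are an error.
    """
    path = Path(path)
    if path.suffix == ".xml":
        case_id = path.stem
        anns, _ = _parse_case_xml(path, case_id, taxonomy, 0)
        return AnnotationSet(anns, [CaseRecord(case_id)])
    manifest = json.loads((path / "manifest.json").read_text())
    cases, annotations = [], []
    next_id = 0
    for entry in manifest["cases"]:
        rec = CaseRecord(
            entry["case_id"],
            image_path=str(path / entry["image"]) if "image" in entry else None,
            spacing=entry.get("spacing", manifest.get("spacing", 0.24)),
        )
        cases.append(rec)
        anns, next_id = _parse_case_xml(
            path / entry["annotations"], rec.case_id, taxonomy, next_id
        )
        annotations.extend(anns)
    return AnnotationSet(annotations, cases)


# ---------------------------------------------------------------------------
# Split


def split_by_case(
    annset: AnnotationSet,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitSpec:
    """Assign whole cases to train/validation/test.

    Cases are shuffled by a seeded permutation of the sorted case-id
    list (so the split depends only on case ids and the seed, never on
    annotation order) and cut so that the cumulative annotation count
    best matches the target fractions; a case straddling a boundary goes
    to the side holding its midpoint.  Exact fractions are generally
    unattainable at case granularity; realized fractions are logged.
    Every partition receives at least one case.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    case_ids = sorted(c.case_id for c in annset.cases)
    if len(case_ids) < 3:
        raise ValueError("need at least 3 cases to form 3 partitions")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    # ≥1 annotation-worth per case so empty cases still occupy space
    weights = {cid: 0 for cid in case_ids}
    for a in annset.annotations:
        weights[a.case_id] += 1
    w = np.array([max(weights[cid], 1) for cid in order], dtype=float)
    total = w.sum()
    bounds = (fractions[0] * total, (fractions[0] + fractions[1]) * total)
    cum = np.cumsum(w)
    mid = cum - w / 2
    assignment: dict[str, str] = {}
    parts: list[list[str]] = [[], [], []]
    for cid, m in zip(order, mid):
        p = 0 if m < bounds[0] else (1 if m < bounds[1] else 2)
        parts[p].append(cid)
    # enforce non-empty partitions by borrowing a boundary case
    for p in (1, 2, 0):
        if not parts[p]:
            donor = max((0, 1, 2), key=lambda q: len(parts[q]))
            parts[p].append(parts[donor].pop())
    for p, name in enumerate(SplitSpec.PARTITIONS):
        for cid in parts[p]:
            assignment[cid] = name
    realized = [
        sum(weights[c] for c in parts[p]) / max(sum(weights.values()), 1)
        for p in range(3)
    ]
    logger.info(
        "split realized annotation fractions: train=%.3f val=%.3f test=%.3f",
        *realized,
    )
    return SplitSpec(tuple(fractions), seed, assignment)


# ---------------------------------------------------------------------------
# Rasterization


@dataclass
class LabeledImage:
    """An RGB raster with a sparse integer label mask."""

    pixels: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) uint8, UNANNOTATED where unlabeled
    spacing: float  # μm/pixel
    case_id: str
    dense_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.labels.shape:
            raise ValueError("pixels and labels must share height and width")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def rasterize(
    annset: AnnotationSet,
    case_id: str,
    shape: tuple[int, int],
    spacing: float | None = None,
) -> np.ndarray:
    """Rasterize one case's polygons to a label mask.

    Vertices (stored at the case's base spacing) are scaled by
    base_spacing / spacing before the pixel-center test.  Pixels inside
    no polygon get the reserved unannotated value; where polygons
    overlap, the highest annotation id wins (last drawn).
    """
    rec = annset.case(case_id)
    spacing = rec.spacing if spacing is None else spacing
    scale = rec.spacing / spacing
    h, w = shape
    labels = np.full((h, w), UNANNOTATED, dtype=np.uint8)
    anns = sorted(annset.for_case(case_id), key=lambda a: a.annotation_id)
    for a in anns:
        verts = np.asarray(a.vertices, dtype=float) * scale
        poly = Polygon(verts)
        if not poly.is_valid or poly.is_empty:
            raise ValueError(
                f"annotation {a.annotation_id} of case {case_id!r} is not a simple polygon"
            )
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(int(np.floor(minx - 0.5)), 0), min(int(np.ceil(maxx)), w)
        r0, r1 = max(int(np.floor(miny - 0.5)), 0), min(int(np.ceil(maxy)), h)
        if c1 <= c0 or r1 <= r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = shapely.contains_xy(
            poly, cols.ravel() + 0.5, rows.ravel() + 0.5
        ).reshape(rows.shape)
        sub = labels[r0:r1, c0:c1]
        sub[inside] = a.class_id
    return labels
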
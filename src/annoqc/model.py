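"""Annotation data model, data dictionary, and project JSON / GeoJSON I/O.

Annotations on a whole-slide image (WSI) are records carrying identity
(annotation, slide and annotator IDs), provenance (stain type, timestamp)
and a geometric construct: a bounding box, a point or circle, a polygon,
a line, or free text.  A :class:`DataDictionary` is the project's reference
document: which labels exist, at which level (case / region / cell /
descriptive), which constructs each label may use, and how many boxes and
annotators each slide needs.  Validation against the dictionary never
mutates records; every violation is reported as an :class:`Issue`.

Coordinates are 0-based base-resolution pixels, origin top-left, x
rightward, y downward.  Polygon rings are stored unclosed (closure is
implicit); GeoJSON export closes them explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry import Polygon as _ShapelyPolygon

SCHEMA_VERSION = "1.0"

LEVELS = ("case", "region", "cell", "descriptive")
CONSTRUCTS = ("bounding_box", "point", "circle", "polygon", "line", "text")

#: Documented issue rule catalogue.  Every Issue.rule_id is one of these.
RULES = {
    "GEOMETRY_ARITY": "geometry vertex count does not match the construct",
    "NONFINITE_COORD": "coordinate is NaN/inf or negative",
    "SELF_INTERSECTION": "polygon ring self-intersects",
    "UNKNOWN_CONSTRUCT": "construct kind is not recognised",
    "UNKNOWN_LEVEL": "annotation level is not recognised",
    "UNKNOWN_LABEL": "feature name absent from the data dictionary",
    "CONSTRUCT_NOT_ALLOWED": "construct not allowed for this label",
    "LEVEL_MISMATCH": "record level differs from the label's dictionary level",
    "OUT_OF_BOUNDS": "coordinates fall outside the slide extent",
    "DUPLICATE_ID": "annotation_id used by more than one record",
    "MISSING_FIELD": "required record field absent or malformed",
    "EMPTY_PROJECT": "no annotation records found",
    "NO_TISSUE_MASK": "tissue mask unavailable; box area used as denominator",
    "NO_TISSUE_IN_BOX": "box contains no tissue; exhaustiveness undefined",
    "STAGE_FAILURE": "a QC stage failed on this slide and was skipped",
    "INCOMPLETE": "slide does not satisfy completeness requirements",
    "EXHAUSTIVENESS_LOW": "box coverage below the exhaustiveness threshold",
}


def utc_now_iso() -> str:
    """Current UTC time as an ISO 8601 string (second precision)."""
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class Label:
    """One dictionary label.

    ``ordinal_group``/``ordinal_rank`` place the label in an ordered chain
    (e.g. nuclear pleomorphism NP1 < NP2 < NP3) used by weighted kappa;
    ``merge_parent`` names the label it coarsens to in merged analyses
    (e.g. NP1/NP2/NP3 -> tumour).
    """

    name: str
    level: str
    ordinal_group: Optional[str] = None
    ordinal_rank: Optional[int] = None
    merge_parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r} for label {self.name!r}")
        if (self.ordinal_group is None) != (self.ordinal_rank is None):
            raise ValueError(
                f"label {self.name!r}: ordinal_rank and ordinal_group "
                "must be given together"
            )


@dataclass
class DataDictionary:
    """Project annotation dictionary: labels, allowed constructs, requirements.

    ``labels`` order is meaningful — it fixes row/column order of confusion
    matrices.  ``required_region_boxes`` / ``required_cell_boxes`` /
    ``required_annotators`` drive the completeness check;
    ``exhaustiveness_threshold`` (percent) flags under-annotated boxes.
    """

    labels: list[Label]
    allowed_constructs: dict[str, list[str]] = field(default_factory=dict)
    required_region_boxes: int = 0
    required_cell_boxes: int = 0
    required_annotators: int = 1
    style: dict[str, dict] = field(default_factory=dict)
    exhaustiveness_threshold: float = 50.0

    def __post_init__(self) -> None:
        names = [lab.name for lab in self.labels]
        if len(names) != len(set(names)):
            raise ValueError("duplicate label names in dictionary")
        for key in list(self.allowed_constructs) + list(self.style):
            if key not in names:
                raise ValueError(f"constructs/style key {key!r} is not a label")
        for lab, cons in self.allowed_constructs.items():
            bad = set(cons) - set(CONSTRUCTS)
            if bad:
                raise ValueError(f"unknown constructs {bad} for label {lab!r}")
        if not 0.0 <= self.exhaustiveness_threshold <= 100.0:
            raise ValueError("exhaustiveness_threshold must be in [0, 100]")
        if self.required_region_boxes < 0 or self.required_cell_boxes < 0:
            raise ValueError("required box counts must be non-negative")
        if self.required_annotators < 1:
            raise ValueError("required_annotators must be positive")
        # ordinal chains must be contiguous 1..k
        groups: dict[str, list[int]] = {}
        for lab in self.labels:
            if lab.ordinal_group is not None:
                groups.setdefault(lab.ordinal_group, []).append(lab.ordinal_rank)
        for grp, ranks in groups.items():
            if sorted(ranks) != list(range(1, len(ranks) + 1)):
                raise ValueError(
                    f"ordinal group {grp!r} ranks {sorted(ranks)} are not 1..k"
                )

    # -- lookups -------------------------------------------------------
    def label_names(self) -> list[str]:
        return [lab.name for lab in self.labels]

    def get(self, name: str) -> Optional[Label]:
        for lab in self.labels:
            if lab.name == name:
                return lab
        return None

    def labels_at(self, level: str) -> list[Label]:
        return [lab for lab in self.labels if lab.level == level]

    def merge_root(self, name: str) -> str:
        """Follow merge_parent links to the terminal label name.

        Raises ``ValueError`` on a cycle or a parent missing from the
        dictionary.
        """
        seen = []
        current = name
        while True:
            lab = self.get(current)
            if lab is None:
                raise ValueError(f"merge chain reaches unknown label {current!r}")
            if lab.merge_parent is None:
                return current
            if current in seen:
                raise ValueError(f"merge cycle involving label {current!r}")
            seen.append(current)
            current = lab.merge_parent

    # -- (de)serialisation --------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "labels": [
                {
                    "name": lab.name,
                    "level": lab.level,
                    "ordinal_group": lab.ordinal_group,
                    "ordinal_rank": lab.ordinal_rank,
                    "merge_parent": lab.merge_parent,
                }
                for lab in self.labels
            ],
            "allowed_constructs": self.allowed_constructs,
            "required_region_boxes": self.required_region_boxes,
            "required_cell_boxes": self.required_cell_boxes,
            "required_annotators": self.required_annotators,
            "style": self.style,
            "exhaustiveness_threshold": self.exhaustiveness_threshold,
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "DataDictionary":
        labels = [
            Label(
                name=entry["name"],
                level=entry["level"],
                ordinal_group=entry.get("ordinal_group"),
                ordinal_rank=entry.get("ordinal_rank"),
                merge_parent=entry.get("merge_parent"),
            )
            for entry in doc["labels"]
        ]
        return cls(
            labels=labels,
            allowed_constructs={
                k: list(v) for k, v in doc.get("allowed_constructs", {}).items()
            },
            required_region_boxes=int(doc.get("required_region_boxes", 0)),
            required_cell_boxes=int(doc.get("required_cell_boxes", 0)),
            required_annotators=int(doc.get("required_annotators", 1)),
            style={k: dict(v) for k, v in doc.get("style", {}).items()},
            exhaustiveness_threshold=float(doc.get("exhaustiveness_threshold", 50.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DataDictionary":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class SlideContext:
    """Physical context of one slide: resolution and pixel extent."""

    slide_id: str
    microns_per_pixel: float
    width_px: int
    height_px: int
    tissue_mask_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")

    def to_json_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "microns_per_pixel": self.microns_per_pixel,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "tissue_mask_path": self.tissue_mask_path,
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "SlideContext":
        return cls(
            slide_id=doc["slide_id"],
            microns_per_pixel=float(doc["microns_per_pixel"]),
            width_px=int(doc["width_px"]),
            height_px=int(doc["height_px"]),
            tissue_mask_path=doc.get("tissue_mask_path"),
        )


@dataclass(frozen=True)
class Issue:
    """One logged QC finding, tied to an annotation and a slide."""

    annotation_id: str
    wsi_id: str
    logged_date: str
    rule_id: str
    severity: str
    description: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULES:
            raise ValueError(f"rule_id {self.rule_id!r} not in the rule catalogue")
        if self.severity not in ("error", "warning"):
            raise ValueError("severity must be 'error' or 'warning'")


def make_issue(
    rule_id: str,
    description: str,
    *,
    wsi_id: str,
    annotation_id: str = "",
    severity: str = "error",
    logged_date: Optional[str] = None,
) -> Issue:
    return Issue(
        annotation_id=annotation_id,
        wsi_id=wsi_id,
        logged_date=logged_date or utc_now_iso(),
        rule_id=rule_id,
        severity=severity,
        description=description,
    )


@dataclass
class AnnotationRecord:
    """One annotated construct on a slide.

    ``geometry`` is a list of (x, y) vertices whose arity depends on the
    construct: point = 1 vertex; circle = centre vertex plus ``radius_px``;
    bounding_box = two opposite corners; polygon = unclosed ring of >= 3
    vertices; line = chain of >= 2 vertices; text/case-level records carry
    no geometry.
    """

    annotation_id: str
    slide_id: str
    annotator_id: str
    stain_type: str
    level: str
    construct: str
    feature_name: str
    geometry: list[tuple[float, float]] = field(default_factory=list)
    radius_px: Optional[float] = None
    text_value: Optional[str] = None
    created_at: str = field(default_factory=utc_now_iso)

    # -- structural validity ------------------------------------------
    def structural_problems(self) -> list[tuple[str, str]]:
        """Return (rule_id, description) for every structural violation."""
        problems: list[tuple[str, str]] = []
        if self.level not in LEVELS:
            problems.append(("UNKNOWN_LEVEL", f"level {self.level!r} not recognised"))
        if self.construct not in CONSTRUCTS:
            problems.append(
                ("UNKNOWN_CONSTRUCT", f"construct {self.construct!r} not recognised")
            )
            return problems  # arity rules below are construct-specific

        for x, y in self.geometry:
            if not (math.isfinite(x) and math.isfinite(y)) or x < 0 or y < 0:
                problems.append(
                    ("NONFINITE_COORD", f"coordinate ({x}, {y}) invalid")
                )
                return problems

        n = len(self.geometry)
        if self.construct == "point" and n != 1:
            problems.append(("GEOMETRY_ARITY", f"point needs 1 vertex, got {n}"))
        elif self.construct == "circle":
            if n != 1:
                problems.append(("GEOMETRY_ARITY", f"circle needs 1 centre, got {n}"))
            elif self.radius_px is None or self.radius_px <= 0:
                problems.append(("GEOMETRY_ARITY", "circle needs a positive radius"))
        elif self.construct == "bounding_box":
            if n != 2:
                problems.append(("GEOMETRY_ARITY", f"box needs 2 corners, got {n}"))
            else:
                (x0, y0), (x1, y1) = self.geometry
                if x0 == x1 or y0 == y1:
                    problems.append(
                        ("GEOMETRY_ARITY", "bounding box has zero extent")
                    )
        elif self.construct == "polygon":
            if n < 3:
                problems.append(
                    ("GEOMETRY_ARITY", f"polygon needs >= 3 vertices, got {n}")
                )
            else:
                ring = _ShapelyPolygon(self.geometry)
                if not ring.is_valid or ring.area == 0.0:
                    problems.append(
                        ("SELF_INTERSECTION", "polygon ring is self-intersecting "
                                              "or degenerate")
                    )
        elif self.construct == "line" and n < 2:
            problems.append(("GEOMETRY_ARITY", f"line needs >= 2 vertices, got {n}"))
        elif self.construct == "text" and n != 0:
            problems.append(("GEOMETRY_ARITY", "text construct carries no geometry"))
        return problems

    def box_corners(self) -> tuple[float, float, float, float]:
        """Normalised (xmin, ymin, xmax, ymax) for a bounding_box record."""
        (x0, y0), (x1, y1) = self.geometry
        return min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)

    # -- (de)serialisation --------------------------------------------
    def to_json_dict(self) -> dict:
        doc = {
            "annotation_id": self.annotation_id,
            "slide_id": self.slide_id,
            "annotator_id": self.annotator_id,
            "stain_type": self.stain_type,
            "level": self.level,
            "construct": self.construct,
            "feature_name": self.feature_name,
            "geometry": [[x, y] for x, y in self.geometry],
            "text_value": self.text_value,
            "created_at": self.created_at,
        }
        if self.radius_px is not None:
            doc["radius_px"] = self.radius_px
        return doc

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "AnnotationRecord":
        return cls(
            annotation_id=str(doc["annotation_id"]),
            slide_id=str(doc["slide_id"]),
            annotator_id=str(doc["annotator_id"]),
            stain_type=str(doc.get("stain_type", "")),
            level=str(doc["level"]),
            construct=str(doc["construct"]),
            feature_name=str(doc["feature_name"]),
            geometry=[(float(x), float(y)) for x, y in doc.get("geometry", [])],
            radius_px=(
                float(doc["radius_px"]) if doc.get("radius_px") is not None else None
            ),
            text_value=doc.get("text_value"),
            created_at=str(doc.get("created_at", "")),
        )


# ---------------------------------------------------------------------
# Project JSON dialect
# ---------------------------------------------------------------------

def load_annotation_file(
    path, dictionary: Optional[DataDictionary] = None
) -> tuple[list[AnnotationRecord], list[Issue]]:
    """Read a project annotation file.

    Structurally invalid records are rejected with an error Issue, never
    silently dropped; record order is preserved.  If a dictionary is given,
    dictionary conformance issues are appended (see :func:`validate`).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, Mapping) or "annotations" not in doc:
        raise ValueError(f"{path}: not a project annotation document")
    slide_id = str(doc.get("slide_id", ""))
    records: list[AnnotationRecord] = []
    issues: list[Issue] = []
    for i, entry in enumerate(doc["annotations"]):
        try:
            rec = AnnotationRecord.from_json_dict(entry)
        except (KeyError, TypeError, ValueError) as exc:
            issues.append(
                make_issue(
                    "MISSING_FIELD",
                    f"record #{i}: {exc}",
                    wsi_id=slide_id or "unknown",
                    annotation_id=str(entry.get("annotation_id", ""))
                    if isinstance(entry, Mapping)
                    else "",
                )
            )
            continue
        problems = rec.structural_problems()
        if problems:
            for rule, desc in problems:
                issues.append(
                    make_issue(
                        rule,
                        desc,
                        wsi_id=rec.slide_id or slide_id or "unknown",
                        annotation_id=rec.annotation_id,
                    )
                )
            continue
        records.append(rec)
    if dictionary is not None:
        issues.extend(validate(records, dictionary))
    return records, issues


def save_annotation_file(
    records: Sequence[AnnotationRecord], path, slide_id: Optional[str] = None
) -> None:
    """Write records to the project JSON dialect; load() round-trips exactly."""
    if slide_id is None:
        slide_id = records[0].slide_id if records else ""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "slide_id": slide_id,
        "annotations": [rec.to_json_dict() for rec in records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def validate(
    records: Sequence[AnnotationRecord],
    dictionary: DataDictionary,
    slide: Optional[SlideContext] = None,
    logged_date: Optional[str] = None,
) -> list[Issue]:
    """Check records against the data dictionary; one Issue per violation.

    Pure: records are never mutated.  An empty return means the set is
    fully conformant.
    """
    issues: list[Issue] = []

    def emit(rule, desc, rec, severity="error"):
        issues.append(
            make_issue(
                rule,
                desc,
                wsi_id=rec.slide_id or "unknown",
                annotation_id=rec.annotation_id,
                severity=severity,
                logged_date=logged_date,
            )
        )

    by_id: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.annotation_id, []).append(rec)

        label = dictionary.get(rec.feature_name)
        if label is None:
            emit(
                "UNKNOWN_LABEL",
                f"feature name {rec.feature_name!r} not in dictionary",
                rec,
            )
            continue
        if rec.level != label.level:
            emit(
                "LEVEL_MISMATCH",
                f"record level {rec.level!r} but label {label.name!r} "
                f"is {label.level}-level",
                rec,
            )
        allowed = dictionary.allowed_constructs.get(rec.feature_name)
        if allowed is not None and rec.construct not in allowed:
            emit(
                "CONSTRUCT_NOT_ALLOWED",
                f"construct {rec.construct!r} not allowed for "
                f"{rec.feature_name!r} (allowed: {sorted(allowed)})",
                rec,
            )
        if slide is not None and rec.geometry:
            xs = [x for x, _ in rec.geometry]
            ys = [y for _, y in rec.geometry]
            if (
                min(xs) < 0
                or min(ys) < 0
                or max(xs) > slide.width_px
                or max(ys) > slide.height_px
            ):
                emit(
                    "OUT_OF_BOUNDS",
                    f"geometry outside slide extent "
                    f"{slide.width_px}x{slide.height_px}",
                    rec,
                )

    for ann_id, recs in by_id.items():
        if len(recs) > 1:
            for rec in recs:
                emit(
                    "DUPLICATE_ID",
                    f"annotation_id {ann_id!r} shared by {len(recs)} records",
                    rec,
                )
    return issues


def merge_labels(
    records: Sequence[AnnotationRecord], dictionary: DataDictionary
) -> list[AnnotationRecord]:
    """Relabel records to their merge_parent root (coarsened analysis).

    Idempotent and record-count preserving; raises on a merge cycle.
    Used e.g. to collapse pleomorphism grades NP1/NP2/NP3 into a single
    tumour class before computing agreement without grade categorisation.
    """
    out = []
    for rec in records:
        if dictionary.get(rec.feature_name) is None:
            out.append(rec)
            continue
        root = dictionary.merge_root(rec.feature_name)
        out.append(rec if root == rec.feature_name else replace(rec, feature_name=root))
    return out


# ---------------------------------------------------------------------
# GeoJSON interoperability (RFC 7946 dialect)
# ---------------------------------------------------------------------

def _closed_ring(geometry: Sequence[tuple[float, float]]) -> list[list[float]]:
    ring = [[float(x), float(y)] for x, y in geometry]
    if ring and ring[0] != ring[-1]:
        ring.append(list(ring[0]))
    return ring


def export_geojson(
    records: Sequence[AnnotationRecord],
    dictionary: Optional[DataDictionary] = None,
) -> dict:
    """Convert records to a GeoJSON FeatureCollection.

    Polygons and boxes become Polygon features with explicitly closed
    rings, points and circles become Point features (circles carry a
    ``radius_px`` property), lines become LineString features, and
    text / case-level records become geometry-less features.  Properties
    preserve all identity fields plus the dictionary display style.
    """
    features = []
    for rec in records:
        props = {
            "annotation_id": rec.annotation_id,
            "slide_id": rec.slide_id,
            "annotator_id": rec.annotator_id,
            "stain_type": rec.stain_type,
            "level": rec.level,
            "construct": rec.construct,
            "feature_name": rec.feature_name,
            "created_at": rec.created_at,
        }
        if rec.text_value is not None:
            props["text_value"] = rec.text_value
        if dictionary is not None and rec.feature_name in dictionary.style:
            props["style"] = dictionary.style[rec.feature_name]

        geom: Optional[dict]
        if rec.construct == "polygon":
            geom = {"type": "Polygon", "coordinates": [_closed_ring(rec.geometry)]}
        elif rec.construct == "bounding_box":
            x0, y0, x1, y1 = rec.box_corners()
            geom = {
                "type": "Polygon",
                "coordinates": [
                    [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                ],
            }
            props["box_corners"] = [[c for c in pt] for pt in rec.geometry]
        elif rec.construct in ("point", "circle"):
            geom = {"type": "Point", "coordinates": list(rec.geometry[0])}
            if rec.construct == "circle":
                props["radius_px"] = rec.radius_px
        elif rec.construct == "line":
            geom = {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in rec.geometry],
            }
        else:  # text / case-level descriptive record
            geom = None
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    return {"type": "FeatureCollection", "features": features}


def import_geojson(doc: Mapping) -> list[AnnotationRecord]:
    """Inverse of :func:`export_geojson` for documents it produced."""
    if doc.get("type") != "FeatureCollection":
        raise ValueError("not a GeoJSON FeatureCollection")
    records = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        construct = props["construct"]
        geom = feat.get("geometry")
        geometry: list[tuple[float, float]] = []
        radius = None
        if construct == "polygon" and geom is not None:
            ring = geom["coordinates"][0]
            if len(ring) > 1 and ring[0] == ring[-1]:
                ring = ring[:-1]
            geometry = [(float(x), float(y)) for x, y in ring]
        elif construct == "bounding_box":
            geometry = [
                (float(x), float(y)) for x, y in props["box_corners"]
            ]
        elif construct in ("point", "circle") and geom is not None:
            geometry = [tuple(float(c) for c in geom["coordinates"])]
            if construct == "circle":
                radius = float(props["radius_px"])
        elif construct == "line" and geom is not None:
            geometry = [(float(x), float(y)) for x, y in geom["coordinates"]]
        records.append(
            AnnotationRecord(
                annotation_id=props["annotation_id"],
                slide_id=props["slide_id"],
                annotator_id=props["annotator_id"],
                stain_type=props.get("stain_type", ""),
                level=props["level"],
                construct=construct,
                feature_name=props["feature_name"],
                geometry=geometry,
                radius_px=radius,
                text_value=props.get("text_value"),
                created_at=props.get("created_at", ""),
            )
        )
    return records
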
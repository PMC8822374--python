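"""Per-slide annotation QC metrics: completeness, exhaustiveness, diversity.

Completeness checks the slide against the protocol's required counts of
region-level boxes, cell-level boxes, and annotators.  Exhaustiveness is
the percentage of tissue inside a designated region box that is covered
by region annotations (overlaps counted once).  Diversity is the number
of distinct region types annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .model import AnnotationRecord, DataDictionary, Issue, SlideContext, make_issue
from .geometry import record_geometry
from .tissue import TissueMask

#: Labels that mark ambiguous structures; they count as annotated tissue
#: for exhaustiveness but are not a region "type" for diversity.
UNKNOWN_LABEL_NAMES = frozenset({"unknown", "unknown_region"})


@dataclass
class CompletenessResult:
    complete: bool
    deficits: list[tuple[str, int, int]] = field(default_factory=list)
    """(requirement, expected, observed) for every unmet requirement."""


@dataclass
class ExhaustivenessResult:
    box_id: str
    percentage: Optional[float]  # None when no tissue in box
    denominator_px2: float
    flagged: bool
    warnings: list[Issue] = field(default_factory=list)


def completeness(
    records: Sequence[AnnotationRecord], dictionary: DataDictionary
) -> CompletenessResult:
    """Check a slide's records against the protocol's required counts.

    Counts bounding boxes at region and cell level and distinct
    annotators; a deficit is reported for each requirement with observed
    count below the dictionary's required count.
    """
    n_region_boxes = sum(
        1
        for r in records
        if r.construct == "bounding_box" and r.level == "region"
    )
    n_cell_boxes = sum(
        1 for r in records if r.construct == "bounding_box" and r.level == "cell"
    )
    n_annotators = len({r.annotator_id for r in records})
    deficits = []
    for name, expected, observed in (
        ("region_boxes", dictionary.required_region_boxes, n_region_boxes),
        ("cell_boxes", dictionary.required_cell_boxes, n_cell_boxes),
        ("annotators", dictionary.required_annotators, n_annotators),
    ):
        if observed < expected:
            deficits.append((name, expected, observed))
    return CompletenessResult(complete=not deficits, deficits=deficits)


def exhaustiveness(
    box: AnnotationRecord,
    regions: Sequence[AnnotationRecord],
    mask: Optional[TissueMask],
    slide: SlideContext,
    dictionary: Optional[DataDictionary] = None,
    logged_date: Optional[str] = None,
) -> ExhaustivenessResult:
    """Percentage of tissue inside a region box covered by region annotations.

    percentage = 100 * area(union(regions) ∩ box ∩ tissue)
                       / area(box ∩ tissue)

    Region polygons are clipped to the box and unioned first, so overlaps
    never double-count and annotation spilling outside the box does not
    inflate the numerator.  With no tissue mask the denominator falls
    back to the full box area and a warning is attached; a box with zero
    tissue yields percentage None (not applicable).
    """
    if box.construct != "bounding_box":
        raise ValueError("exhaustiveness needs a bounding_box record")
    x0, y0, x1, y1 = box.box_corners()
    box_geom = shapely_box(x0, y0, x1, y1)
    shapes = [
        g
        for g in (record_geometry(r) for r in regions if r.level == "region")
        if g is not None
    ]
    covered = unary_union(shapes).intersection(box_geom) if shapes else None
    warnings: list[Issue] = []
    threshold = (
        dictionary.exhaustiveness_threshold if dictionary is not None else 50.0
    )

    if mask is None:
        warnings.append(
            make_issue(
                "NO_TISSUE_MASK",
                f"box {box.annotation_id}: no tissue mask; "
                "using box area as denominator",
                wsi_id=slide.slide_id,
                annotation_id=box.annotation_id,
                severity="warning",
                logged_date=logged_date,
            )
        )
        denom = box_geom.area
        numer = covered.area if covered is not None else 0.0
    else:
        # mask-pixel centres inside the box
        ox, oy = mask.origin
        h, w = mask.mask.shape
        cx = ox + (np.arange(w) + 0.5) * mask.downsample
        cy = oy + (np.arange(h) + 0.5) * mask.downsample
        col_sel = (cx >= x0) & (cx < x1)
        row_sel = (cy >= y0) & (cy < y1)
        sub = mask.mask[np.ix_(row_sel, col_sel)]
        n_tissue = int(np.count_nonzero(sub))
        denom = n_tissue * mask.downsample**2
        if n_tissue == 0:
            warnings.append(
                make_issue(
                    "NO_TISSUE_IN_BOX",
                    f"box {box.annotation_id}: no tissue inside box; "
                    "exhaustiveness not applicable",
                    wsi_id=slide.slide_id,
                    annotation_id=box.annotation_id,
                    severity="warning",
                    logged_date=logged_date,
                )
            )
            return ExhaustivenessResult(
                box_id=box.annotation_id,
                percentage=None,
                denominator_px2=0.0,
                flagged=False,
                warnings=warnings,
            )
        if covered is None or covered.is_empty:
            numer = 0.0
        else:
            gx, gy = np.meshgrid(cx[col_sel], cy[row_sel])
            in_cover = contains_xy(covered, gx.ravel(), gy.ravel()).reshape(sub.shape)
            numer = int(np.count_nonzero(in_cover & sub)) * mask.downsample**2

    pct = 100.0 * numer / denom if denom > 0 else 0.0
    pct = min(pct, 100.0)
    return ExhaustivenessResult(
        box_id=box.annotation_id,
        percentage=pct,
        denominator_px2=denom,
        flagged=pct < threshold,
        warnings=warnings,
    )


def diversity(
    records: Sequence[AnnotationRecord], dictionary: DataDictionary
) -> int:
    """Number of distinct region types annotated on the slide.

    Bounded above by the dictionary's region-label count; "unknown"
    regions are annotated tissue but not a type, so they are excluded.
    """
    region_labels = {lab.name for lab in dictionary.labels_at("region")}
    present = {
        r.feature_name
        for r in records
        if r.level == "region"
        and r.feature_name in region_labels
        and r.feature_name not in UNKNOWN_LABEL_NAMES
    }
    return len(present)
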
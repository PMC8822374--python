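"""Project-level QC orchestration: load -> validate -> metrics -> agreement.

:func:`run_qc` runs the full annotation QC over a project (several
slides, several annotators), producing a :class:`QCReport` with
per-slide metrics, per-pair agreement, aggregate statistics and an
issue log.  A stage failure on one slide is logged as an issue and does
not abort the other slides.  In reproducible mode all timestamps come
from the config, so repeated runs on identical inputs produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as qc_metrics
from .agreement import (
    PairResult,
    PairSummary,
    aggregate_pairs,
    cell_agreement,
    cohens_kappa,
    confusion,
    match_points,
)
from .geometry import RegionSet, px2_to_mm2, record_geometry
from .model import (
    AnnotationRecord,
    DataDictionary,
    Issue,
    SlideContext,
    load_annotation_file,
    make_issue,
    utc_now_iso,
    validate,
)
from .simulate import cell_points_and_labels
from .tissue import TissueMask

logger = logging.getLogger("annoqc")

MATCH_RADIUS_UM_DEFAULT = 3.0


@dataclass
class QCConfig:
    """Pipeline configuration with all defaults in one place."""

    radius_um: float = MATCH_RADIUS_UM_DEFAULT
    kappa_weighting: str = "linear"  # none | linear | quadratic
    exhaustiveness_threshold: Optional[float] = None  # None -> dictionary value
    include_unknown_cells: bool = False
    reproducible: bool = False
    timestamp: str = "1970-01-01T00:00:00Z"  # used when reproducible

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "QCConfig":
        merged = {}
        for section in ("metrics", "agreement", "tissue", "reporting", "paths"):
            merged.update(doc.get(section, {}))
        merged.update({k: v for k, v in doc.items() if not isinstance(v, Mapping)})
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in merged.items() if k in known})

    def now(self) -> str:
        return self.timestamp if self.reproducible else utc_now_iso()


@dataclass
class SlideMetrics:
    slide_id: str
    n_records: int
    complete: bool
    deficits: list[tuple[str, int, int]]
    diversity: int
    exhaustiveness: list[dict]  # box_id, annotator_id, percentage, flagged
    label_stats: list[dict]  # label, level, count, area_px2, area_mm2


@dataclass
class QCReport:
    project_id: str
    generated_at: str
    per_slide: list[SlideMetrics]
    per_pair: list[PairResult]
    summary: Optional[PairSummary]
    issues: list[Issue]

    def to_json_dict(self) -> dict:
        def pair_dict(p: PairResult) -> dict:
            return {
                "slide_id": p.slide_id,
                "annotator_a": p.annotator_a,
                "annotator_b": p.annotator_b,
                "breakdown": {
                    "agreed_pct": p.breakdown.agreed_pct,
                    "disagreed_pct": p.breakdown.disagreed_pct,
                    "missed_pct": p.breakdown.missed_pct,
                    "n_matched": p.breakdown.n_matched,
                    "n_missed_by_a": p.breakdown.n_missed_by_a,
                    "n_missed_by_b": p.breakdown.n_missed_by_b,
                    "applicable": p.breakdown.applicable,
                },
                "confusion": None
                if p.confusion is None
                else {
                    "labels": p.confusion.labels,
                    "counts": p.confusion.counts.tolist(),
                },
                "kappa": p.kappa,
                "kappa_weighting": p.kappa_weighting,
                "region_jsi": [
                    {
                        "label": r.label,
                        "jsi": r.jsi,
                        "union_area_mm2": r.union_area_mm2,
                        "one_sided": r.one_sided,
                    }
                    for r in p.region_rows
                ],
            }

        summary = None
        if self.summary is not None:
            s = self.summary
            summary = {
                "n_pairs": s.n_pairs,
                "mean_agreed_pct": s.mean_agreed_pct,
                "mean_disagreed_pct": s.mean_disagreed_pct,
                "mean_missed_pct": s.mean_missed_pct,
                "pooled_confusion": None
                if s.pooled_confusion is None
                else {
                    "labels": s.pooled_confusion.labels,
                    "counts": s.pooled_confusion.counts.tolist(),
                },
                "pooled_kappa": s.pooled_kappa,
                "kappa_weighting": s.kappa_weighting,
                "mean_jsi_per_label": s.mean_jsi_per_label,
            }
        return {
            "project_id": self.project_id,
            "generated_at": self.generated_at,
            "per_slide": [
                {
                    "slide_id": sm.slide_id,
                    "n_records": sm.n_records,
                    "complete": sm.complete,
                    "deficits": [list(d) for d in sm.deficits],
                    "diversity": sm.diversity,
                    "exhaustiveness": sm.exhaustiveness,
                    "label_stats": sm.label_stats,
                }
                for sm in self.per_slide
            ],
            "per_pair": [pair_dict(p) for p in self.per_pair],
            "summary": summary,
            "issues": [
                {
                    "annotation_id": i.annotation_id,
                    "wsi_id": i.wsi_id,
                    "logged_date": i.logged_date,
                    "rule_id": i.rule_id,
                    "severity": i.severity,
                    "description": i.description,
                }
                for i in self.issues
            ],
        }


def _label_stats(
    records: Sequence[AnnotationRecord], dictionary: DataDictionary, mpp: float
) -> list[dict]:
    """Count and total area per label, to support prioritisation."""
    acc: dict[str, dict] = {}
    for rec in records:
        entry = acc.setdefault(
            rec.feature_name,
            {"label": rec.feature_name, "level": rec.level, "count": 0,
             "area_px2": 0.0},
        )
        entry["count"] += 1
        geom = record_geometry(rec)
        if geom is not None and rec.construct != "bounding_box":
            entry["area_px2"] += geom.area
    order = {name: k for k, name in enumerate(dictionary.label_names())}
    rows = sorted(acc.values(), key=lambda e: order.get(e["label"], len(order)))
    for row in rows:
        row["area_mm2"] = px2_to_mm2(row["area_px2"], mpp)
    return rows


def run_qc(
    annotation_files: Sequence,
    dictionary: DataDictionary,
    slides: Mapping[str, SlideContext],
    config: Optional[QCConfig] = None,
    masks: Optional[Mapping[str, TissueMask]] = None,
    records_override: Optional[Sequence[AnnotationRecord]] = None,
) -> QCReport:
    """Run the full QC pipeline over a project.

    ``annotation_files`` are project-JSON paths (one file per slide and
    annotator is typical); pass ``records_override`` to supply records
    already in memory instead.  ``slides`` maps slide_id to its context;
    ``masks`` optionally maps slide_id to a tissue mask (absent masks
    fall back to box-area denominators with a warning).
    """
    if config is None:
        config = QCConfig()
    masks = masks or {}
    now = config.now()

    records: list[AnnotationRecord] = []
    issues: list[Issue] = []
    if records_override is not None:
        records = list(records_override)
    else:
        for path in annotation_files:
            recs, load_issues = load_annotation_file(path)
            records.extend(recs)
            issues.extend(
                replace(i, logged_date=now) for i in load_issues
            )

    if not records:
        issues.append(
            make_issue(
                "EMPTY_PROJECT",
                "no annotation records in project",
                wsi_id="project",
                severity="warning",
                logged_date=now,
            )
        )
        return QCReport(
            project_id="project",
            generated_at=now,
            per_slide=[],
            per_pair=[],
            summary=None,
            issues=issues,
        )

    from . import agreement as agreement_mod

    by_slide: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_slide.setdefault(rec.slide_id, []).append(rec)

    per_slide: list[SlideMetrics] = []
    per_pair: list[PairResult] = []
    threshold = (
        config.exhaustiveness_threshold
        if config.exhaustiveness_threshold is not None
        else dictionary.exhaustiveness_threshold
    )
    dict_for_exh = replace_threshold(dictionary, threshold)

    for slide_id in sorted(by_slide):
        slide_records = by_slide[slide_id]
        slide = slides.get(slide_id)
        if slide is None:
            issues.append(
                make_issue(
                    "STAGE_FAILURE",
                    f"no slide context for {slide_id}; metrics skipped",
                    wsi_id=slide_id,
                    severity="warning",
                    logged_date=now,
                )
            )
            continue
        try:
            per_slide.append(
                _slide_stage(
                    slide_id, slide_records, dictionary, dict_for_exh,
                    slide, masks.get(slide_id), issues, now,
                )
            )
        except Exception as exc:  # stage isolation: log, continue
            logger.exception("slide stage failed on %s", slide_id)
            issues.append(
                make_issue(
                    "STAGE_FAILURE",
                    f"slide metrics failed: {exc}",
                    wsi_id=slide_id,
                    severity="error",
                    logged_date=now,
                )
            )
            continue

        # agreement over all unordered annotator pairs on this slide
        annotators = sorted({r.annotator_id for r in slide_records})
        radius_px = config.radius_um / slide.microns_per_pixel
        for ia in range(len(annotators)):
            for ib in range(ia + 1, len(annotators)):
                rec_a = [r for r in slide_records
                         if r.annotator_id == annotators[ia]]
                rec_b = [r for r in slide_records
                         if r.annotator_id == annotators[ib]]
                try:
                    per_pair.append(
                        _pair_stage(
                            rec_a, rec_b, annotators[ia], annotators[ib],
                            dictionary, slide, radius_px, config,
                        )
                    )
                except Exception as exc:
                    logger.exception("agreement stage failed on %s", slide_id)
                    issues.append(
                        make_issue(
                            "STAGE_FAILURE",
                            f"agreement failed for pair "
                            f"({annotators[ia]}, {annotators[ib]}): {exc}",
                            wsi_id=slide_id,
                            severity="error",
                            logged_date=now,
                        )
                    )

    issues.extend(validate(records, dictionary, logged_date=now))
    summary = aggregate_pairs(per_pair, dictionary) if per_pair else None
    return QCReport(
        project_id="project",
        generated_at=now,
        per_slide=per_slide,
        per_pair=per_pair,
        summary=summary,
        issues=issues,
    )


def replace_threshold(
    dictionary: DataDictionary, threshold: float
) -> DataDictionary:
    if threshold == dictionary.exhaustiveness_threshold:
        return dictionary
    return DataDictionary(
        labels=dictionary.labels,
        allowed_constructs=dictionary.allowed_constructs,
        required_region_boxes=dictionary.required_region_boxes,
        required_cell_boxes=dictionary.required_cell_boxes,
        required_annotators=dictionary.required_annotators,
        style=dictionary.style,
        exhaustiveness_threshold=threshold,
    )


def _slide_stage(
    slide_id, slide_records, dictionary, dict_for_exh, slide, mask, issues, now
) -> SlideMetrics:
    comp = qc_metrics.completeness(slide_records, dictionary)
    if not comp.complete:
        issues.append(
            make_issue(
                "INCOMPLETE",
                "unmet requirements: "
                + "; ".join(f"{n} {o}/{e}" for n, e, o in comp.deficits),
                wsi_id=slide_id,
                severity="warning",
                logged_date=now,
            )
        )
    region_records = [r for r in slide_records if r.level == "region"]
    div = qc_metrics.diversity(region_records, dictionary)

    exh_rows = []
    boxes = [
        r for r in slide_records
        if r.construct == "bounding_box" and r.level == "region"
    ]
    for box in boxes:
        regions = [
            r for r in region_records
            if r.annotator_id == box.annotator_id and r.construct == "polygon"
        ]
        res = qc_metrics.exhaustiveness(
            box, regions, mask, slide, dict_for_exh, logged_date=now
        )
        issues.extend(res.warnings)
        if res.flagged and res.percentage is not None:
            issues.append(
                make_issue(
                    "EXHAUSTIVENESS_LOW",
                    f"box {box.annotation_id} coverage "
                    f"{res.percentage:.1f}% below threshold "
                    f"{dict_for_exh.exhaustiveness_threshold:.1f}%",
                    wsi_id=slide_id,
                    annotation_id=box.annotation_id,
                    severity="warning",
                    logged_date=now,
                )
            )
        exh_rows.append(
            {
                "box_id": box.annotation_id,
                "annotator_id": box.annotator_id,
                "percentage": res.percentage,
                "flagged": res.flagged,
            }
        )
    return SlideMetrics(
        slide_id=slide_id,
        n_records=len(slide_records),
        complete=comp.complete,
        deficits=comp.deficits,
        diversity=div,
        exhaustiveness=exh_rows,
        label_stats=_label_stats(slide_records, dictionary,
                                 slide.microns_per_pixel),
    )


def _pair_stage(
    rec_a, rec_b, name_a, name_b, dictionary, slide, radius_px, config
) -> PairResult:
    from .agreement import region_agreement

    pts_a, labels_a = cell_points_and_labels(rec_a)
    pts_b, labels_b = cell_points_and_labels(rec_b)
    matching = match_points(pts_a, pts_b, radius_px)
    breakdown = cell_agreement(matching, labels_a, labels_b)
    cm = None
    kappa = None
    if matching.n_matched > 0:
        cm = confusion(
            matching, labels_a, labels_b, dictionary,
            include_unknown=config.include_unknown_cells,
        )
        kappa = cohens_kappa(cm, config.kappa_weighting, dictionary)
    rows = region_agreement(rec_a, rec_b, dictionary, slide)
    return PairResult(
        slide_id=slide.slide_id,
        annotator_a=name_a,
        annotator_b=name_b,
        breakdown=breakdown,
        confusion=cm,
        kappa=kappa,
        kappa_weighting=config.kappa_weighting,
        region_rows=rows,
    )


# ---------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------

def write_report(report: QCReport, out_dir) -> None:
    """Write ``qc_report.json`` plus CSV tables to a directory.

    Files: per_slide_metrics.csv, label_counts_areas.csv,
    region_jsi.csv, cell_confusion_<pair>.csv (one per annotator pair),
    issues.csv.  Re-reading the JSON reproduces the report.
    """
    os.makedirs(out_dir, exist_ok=True)
    doc = report.to_json_dict()
    with open(os.path.join(out_dir, "qc_report.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)

    pd.DataFrame(
        [
            {
                "slide_id": sm.slide_id,
                "n_records": sm.n_records,
                "complete": sm.complete,
                "diversity": sm.diversity,
                "n_boxes_flagged": sum(1 for e in sm.exhaustiveness if e["flagged"]),
            }
            for sm in report.per_slide
        ]
    ).to_csv(os.path.join(out_dir, "per_slide_metrics.csv"), index=False)

    pd.DataFrame(
        [
            {"slide_id": sm.slide_id, **row}
            for sm in report.per_slide
            for row in sm.label_stats
        ]
    ).to_csv(os.path.join(out_dir, "label_counts_areas.csv"), index=False)

    pd.DataFrame(
        [
            {
                "slide_id": p.slide_id,
                "annotator_a": p.annotator_a,
                "annotator_b": p.annotator_b,
                "label": r.label,
                "jsi": r.jsi,
                "union_area_mm2": r.union_area_mm2,
                "one_sided": r.one_sided,
            }
            for p in report.per_pair
            for r in p.region_rows
        ]
    ).to_csv(os.path.join(out_dir, "region_jsi.csv"), index=False)

    for p in report.per_pair:
        if p.confusion is None:
            continue
        name = f"cell_confusion_{p.slide_id}_{p.annotator_a}_vs_{p.annotator_b}.csv"
        pd.DataFrame(
            p.confusion.counts, index=p.confusion.labels,
            columns=p.confusion.labels,
        ).to_csv(os.path.join(out_dir, name))

    pd.DataFrame([i.__dict__ for i in report.issues]).to_csv(
        os.path.join(out_dir, "issues.csv"), index=False
    )


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
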
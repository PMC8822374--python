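"""Synthetic ground truth and simulated annotators for QC testing.

Real multi-annotator WSI annotation sets are rarely shareable, so every
metric in this package is exercised against simulated projects with
known parameters.  A :class:`GroundTruth` holds the "correct" regions
and cells of a slide; an :class:`AnnotatorProfile` describes a
stochastic annotator who misses true cells, adds spurious ones,
confuses labels (by default concentrated on adjacent nuclear
pleomorphism grades, the hardest distinction in practice) and jitters
positions and boundaries.  Two simulated annotators are conditionally
independent given the truth, which gives closed-form expectations for
the missed-cell fraction and for Cohen's kappa
(:func:`analytic_expected_kappa`) that recovery tests check against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .model import AnnotationRecord, DataDictionary, Label, SlideContext
from .agreement import kappa_weight_matrix

TRUTH_ANNOTATOR = "truth"

#: Cell labels of the default breast dictionary, in declaration order.
CELL_LABELS = (
    "tumour_np1",
    "tumour_np2",
    "tumour_np3",
    "TILs",
    "stromal_cell",
    "normal_epithelial_cell",
)
REGION_LABELS = (
    "tumour",
    "stroma",
    "tumour_associated_stroma",
    "normal_epithelial",
)


def default_breast_dictionary(
    required_region_boxes: int = 2,
    required_cell_boxes: int = 1,
    required_annotators: int = 2,
    exhaustiveness_threshold: float = 50.0,
) -> DataDictionary:
    """Breast-style annotation dictionary.

    Regions: tumour, stroma, tumour-associated stroma, normal
    epithelium.  Cells: tumour nuclei graded by nuclear pleomorphism
    (NP1 < NP2 < NP3, one ordinal chain, merging to a single
    tumour-cell class for grade-free analyses), TILs, stromal cells,
    normal epithelial cells, and an "unknown" escape label.
    """
    labels = [
        Label("region_box", "region"),
        Label("cell_box", "cell"),
        *[Label(name, "region") for name in REGION_LABELS],
        Label("unknown_region", "region"),
        Label("tumour_cell", "cell"),
        Label("tumour_np1", "cell", "nuclear-pleomorphism", 1, "tumour_cell"),
        Label("tumour_np2", "cell", "nuclear-pleomorphism", 2, "tumour_cell"),
        Label("tumour_np3", "cell", "nuclear-pleomorphism", 3, "tumour_cell"),
        Label("TILs", "cell"),
        Label("stromal_cell", "cell"),
        Label("normal_epithelial_cell", "cell"),
        Label("unknown", "cell"),
    ]
    allowed = {"region_box": ["bounding_box"], "cell_box": ["bounding_box"]}
    for name in (*REGION_LABELS, "unknown_region"):
        allowed[name] = ["polygon"]
    for name in (*CELL_LABELS, "tumour_cell", "unknown"):
        allowed[name] = ["point", "circle"]
    palette = {
        "tumour": "#d62728", "stroma": "#2ca02c",
        "tumour_associated_stroma": "#98df8a", "normal_epithelial": "#1f77b4",
        "tumour_np1": "#ffbb78", "tumour_np2": "#ff7f0e",
        "tumour_np3": "#8c2d04", "TILs": "#9467bd",
        "stromal_cell": "#2ca02c", "normal_epithelial_cell": "#1f77b4",
    }
    style = {
        k: {"line_colour": v, "linewidth": 2, "line_style": "solid"}
        for k, v in palette.items()
    }
    return DataDictionary(
        labels=labels,
        allowed_constructs=allowed,
        required_region_boxes=required_region_boxes,
        required_cell_boxes=required_cell_boxes,
        required_annotators=required_annotators,
        style=style,
        exhaustiveness_threshold=exhaustiveness_threshold,
    )


def default_prevalence() -> dict[str, float]:
    """Default cell-label prevalence (tumour-rich breast H&E field)."""
    return {
        "tumour_np1": 0.20,
        "tumour_np2": 0.15,
        "tumour_np3": 0.05,
        "TILs": 0.20,
        "stromal_cell": 0.25,
        "normal_epithelial_cell": 0.15,
    }


def default_confusion_kernel(adjacent_np: float = 0.1) -> dict[str, dict[str, float]]:
    """Reported-label kernel with confusion on adjacent pleomorphism grades.

    A true NP-grade nucleus is reported one grade up or down with
    probability ``adjacent_np`` per available neighbour; non-tumour
    labels are reported faithfully.
    """
    kernel: dict[str, dict[str, float]] = {}
    np_chain = ["tumour_np1", "tumour_np2", "tumour_np3"]
    for i, name in enumerate(np_chain):
        row = {name: 1.0}
        for j in (i - 1, i + 1):
            if 0 <= j < len(np_chain):
                row[np_chain[j]] = adjacent_np
                row[name] -= adjacent_np
        kernel[name] = row
    for name in ("TILs", "stromal_cell", "normal_epithelial_cell"):
        kernel[name] = {name: 1.0}
    return kernel


@dataclass
class AnnotatorProfile:
    """Stochastic behaviour of one simulated annotator.

    ``miss_rate``: probability of omitting a true cell (pathologists
    commonly miss cells even in exhaustive box annotation).
    ``spurious_rate``: expected spurious cells per true cell, labels
    drawn from the truth prevalence.  ``confusion_kernel``: per-true-
    label distribution over reported labels.  Jitter sigmas are in base
    pixels.
    """

    annotator_id: str
    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    confusion_kernel: dict[str, dict[str, float]] = field(default_factory=dict)
    position_jitter_sigma: float = 0.0
    boundary_jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")
        if self.position_jitter_sigma < 0 or self.boundary_jitter_sigma < 0:
            raise ValueError("jitter sigmas must be non-negative")
        for true_label, row in self.confusion_kernel.items():
            total = sum(row.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"kernel row for {true_label!r} sums to {total}, not 1"
                )
            if any(p < 0 for p in row.values()):
                raise ValueError("kernel probabilities must be non-negative")


@dataclass
class LayoutParams:
    """Ground-truth layout: slide size, boxes, cells, regions.

    Cells keep a minimum pairwise separation of twice the matching
    radius (24 px at 0.25 um/px) by default, so truth-vs-truth matching
    is unambiguous; set ``min_separation_px`` to 0 for a crowded layout
    that stresses the optimal matcher.
    """

    slide_width: int = 4096
    slide_height: int = 4096
    microns_per_pixel: float = 0.25
    n_region_boxes: int = 2
    n_cell_boxes: int = 1
    box_size_px: int = 1200
    cells_per_box: int = 150
    regions_per_box: int = 4
    region_vertices: int = 12
    min_separation_px: float = 24.0
    label_prevalence: dict[str, float] = field(default_factory=default_prevalence)
    stain_type: str = "H&E"

    def __post_init__(self) -> None:
        total = sum(self.label_prevalence.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"label prevalence sums to {total}, not 1")


@dataclass
class GroundTruth:
    """Truth annotations of one simulated slide, plus its dictionary."""

    slide: SlideContext
    dictionary: DataDictionary
    records: list[AnnotationRecord]
    label_prevalence: dict[str, float]

    def cell_records(self) -> list[AnnotationRecord]:
        return [r for r in self.records if r.construct == "point"]

    def region_records(self) -> list[AnnotationRecord]:
        return [r for r in self.records if r.construct == "polygon"]

    def box_records(self, level: Optional[str] = None) -> list[AnnotationRecord]:
        return [
            r
            for r in self.records
            if r.construct == "bounding_box" and (level is None or r.level == level)
        ]


def _star_polygon(
    rng: np.random.Generator,
    centre: tuple[float, float],
    mean_radius: float,
    n_vertices: int,
) -> list[tuple[float, float]]:
    """Random star-shaped (hence simple) polygon around a centre.

    One vertex per angular sector keeps the angles strictly increasing,
    which makes the ring simple for any radius draw.
    """
    angles = (
        2 * np.pi
        * (np.arange(n_vertices) + rng.uniform(0.1, 0.9, n_vertices))
        / n_vertices
    )
    radii = rng.uniform(0.5, 1.0, n_vertices) * mean_radius
    xs = centre[0] + radii * np.cos(angles)
    ys = centre[1] + radii * np.sin(angles)
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def _place_separated(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_sep: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation."""
    x0, y0, x1, y1 = bounds
    points: list[tuple[float, float]] = []
    if min_sep > 0:
        capacity = ((x1 - x0) / min_sep) * ((y1 - y0) / min_sep)
        if n > capacity:
            raise ValueError(
                f"infeasible density: {n} cells cannot keep "
                f"{min_sep} px separation in this box"
            )
    for _ in range(n):
        for attempt in range(max_tries):
            p = (rng.uniform(x0, x1), rng.uniform(y0, y1))
            if min_sep <= 0 or all(
                (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2
                for q in points
            ):
                points.append(p)
                break
        else:
            raise ValueError(
                "infeasible density: could not place all cells with the "
                "requested minimum separation"
            )
    return np.asarray(points, dtype=float).reshape(-1, 2)


def generate_ground_truth(
    params: Optional[LayoutParams] = None,
    seed: int = 0,
    slide_id: str = "sim-slide",
) -> GroundTruth:
    """Generate one slide's ground-truth annotations, reproducibly.

    Region boxes each receive ``regions_per_box`` star polygons labelled
    round-robin from the region labels; cell boxes receive
    ``cells_per_box`` points with labels drawn from ``label_prevalence``
    and pairwise separation at least ``min_separation_px``.
    """
    if params is None:
        params = LayoutParams()
    rng = np.random.default_rng(seed)
    dictionary = default_breast_dictionary()
    slide = SlideContext(
        slide_id=slide_id,
        microns_per_pixel=params.microns_per_pixel,
        width_px=params.slide_width,
        height_px=params.slide_height,
    )
    records: list[AnnotationRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{slide_id}-truth-{counter:05d}"

    def add(level, construct, feature, geometry, radius=None):
        records.append(
            AnnotationRecord(
                annotation_id=new_id(),
                slide_id=slide_id,
                annotator_id=TRUTH_ANNOTATOR,
                stain_type=params.stain_type,
                level=level,
                construct=construct,
                feature_name=feature,
                geometry=geometry,
                radius_px=radius,
                created_at="1970-01-01T00:00:00Z",
            )
        )

    # non-overlapping boxes on a grid with jittered offsets
    n_boxes = params.n_region_boxes + params.n_cell_boxes
    size = params.box_size_px
    per_row = max(1, params.slide_width // (size + 200))
    box_bounds = []
    for k in range(n_boxes):
        row, col = divmod(k, per_row)
        x0 = min(col * (size + 200) + 100, params.slide_width - size - 1)
        y0 = min(row * (size + 200) + 100, params.slide_height - size - 1)
        if x0 < 0 or y0 < 0:
            raise ValueError("box_size_px too large for the slide")
        box_bounds.append((float(x0), float(y0), float(x0 + size), float(y0 + size)))

    region_bounds = box_bounds[: params.n_region_boxes]
    cell_bounds = box_bounds[params.n_region_boxes:]

    for x0, y0, x1, y1 in region_bounds:
        add("region", "bounding_box", "region_box", [(x0, y0), (x1, y1)])
        mean_r = size / (2.5 * math.sqrt(params.regions_per_box))
        for k in range(params.regions_per_box):
            label = REGION_LABELS[k % len(REGION_LABELS)]
            centre = (
                rng.uniform(x0 + mean_r, x1 - mean_r),
                rng.uniform(y0 + mean_r, y1 - mean_r),
            )
            ring = _star_polygon(rng, centre, mean_r, params.region_vertices)
            add("region", "polygon", label, ring)

    labels = list(params.label_prevalence)
    probs = np.array([params.label_prevalence[k] for k in labels])
    for x0, y0, x1, y1 in cell_bounds:
        add("cell", "bounding_box", "cell_box", [(x0, y0), (x1, y1)])
        pts = _place_separated(
            rng, params.cells_per_box, (x0, y0, x1, y1), params.min_separation_px
        )
        drawn = rng.choice(len(labels), size=len(pts), p=probs)
        for p, li in zip(pts, drawn):
            add("cell", "point", labels[li], [(float(p[0]), float(p[1]))])

    return GroundTruth(
        slide=slide,
        dictionary=dictionary,
        records=records,
        label_prevalence=dict(params.label_prevalence),
    )


def simulate_annotator(
    truth: GroundTruth, profile: AnnotatorProfile
) -> list[AnnotationRecord]:
    """Simulate one annotator's records from the ground truth.

    Each true cell is independently dropped with ``miss_rate``,
    otherwise reported with a label drawn from the confusion-kernel row
    of its true label and a position jittered by isotropic Gaussian
    noise.  Spurious cells (count ~ Poisson(spurious_rate x n_true),
    labels from prevalence) are added uniformly inside the cell boxes.
    Region polygon vertices are jittered and re-sampled until the ring
    is simple.  Boxes are copied verbatim.  Reproducible for a fixed
    profile seed.
    """
    rng = np.random.default_rng(profile.seed)
    out: list[AnnotationRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{truth.slide.slide_id}-{profile.annotator_id}-{counter:05d}"

    def emit(rec: AnnotationRecord, feature=None, geometry=None):
        out.append(
            AnnotationRecord(
                annotation_id=new_id(),
                slide_id=rec.slide_id,
                annotator_id=profile.annotator_id,
                stain_type=rec.stain_type,
                level=rec.level,
                construct=rec.construct,
                feature_name=feature if feature is not None else rec.feature_name,
                geometry=geometry if geometry is not None else list(rec.geometry),
                radius_px=rec.radius_px,
                created_at=rec.created_at,
            )
        )

    n_true_cells = 0
    cell_boxes = []
    for rec in truth.records:
        if rec.construct == "bounding_box":
            emit(rec)
            if rec.level == "cell":
                cell_boxes.append(rec.box_corners())
        elif rec.construct == "polygon":
            ring = rec.geometry
            if profile.boundary_jitter_sigma > 0:
                for _ in range(50):  # rejection-sample until simple
                    jitter = rng.normal(
                        0.0, profile.boundary_jitter_sigma, (len(ring), 2)
                    )
                    cand = [
                        (max(0.0, x + dx), max(0.0, y + dy))
                        for (x, y), (dx, dy) in zip(ring, jitter)
                    ]
                    poly = _ShapelyPolygon(cand)
                    if poly.is_valid and poly.area > 0:
                        ring = cand
                        break
            emit(rec, geometry=[(float(x), float(y)) for x, y in ring])
        elif rec.construct == "point":
            n_true_cells += 1
            if rng.random() < profile.miss_rate:
                continue
            label = rec.feature_name
            row = profile.confusion_kernel.get(label)
            if row:
                names = list(row)
                label = names[rng.choice(len(names), p=list(row.values()))]
            x, y = rec.geometry[0]
            if profile.position_jitter_sigma > 0:
                dx, dy = rng.normal(0.0, profile.position_jitter_sigma, 2)
                x, y = max(0.0, x + dx), max(0.0, y + dy)
            emit(rec, feature=label, geometry=[(float(x), float(y))])
        else:
            emit(rec)

    if profile.spurious_rate > 0 and cell_boxes:
        n_spurious = int(rng.poisson(profile.spurious_rate * n_true_cells))
        labels = list(truth.label_prevalence)
        probs = list(truth.label_prevalence.values())
        template = next(r for r in truth.records if r.construct == "point")
        for _ in range(n_spurious):
            x0, y0, x1, y1 = cell_boxes[rng.choice(len(cell_boxes))]
            pt = (float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1)))
            emit(
                template,
                feature=labels[rng.choice(len(labels), p=probs)],
                geometry=[pt],
            )
    return out


# ---------------------------------------------------------------------
# Closed-form expectations (oracles for recovery tests)
# ---------------------------------------------------------------------

def _kernel_matrix(
    kernel: dict[str, dict[str, float]], labels: Sequence[str]
) -> np.ndarray:
    mat = np.zeros((len(labels), len(labels)))
    for i, t in enumerate(labels):
        row = kernel.get(t, {t: 1.0})
        for name, p in row.items():
            mat[i, labels.index(name)] = p
    return mat


def analytic_expected_kappa(
    kernel_a: dict[str, dict[str, float]],
    kernel_b: dict[str, dict[str, float]],
    prevalence: dict[str, float],
    weighting: str = "none",
    dictionary: Optional[DataDictionary] = None,
) -> Optional[float]:
    """Expected Cohen's kappa of two annotators conditionally independent
    given the truth.

    The joint label distribution over matched cells is
    p(i, j) = sum_t pi_t A(t, i) B(t, j); kappa follows from p and its
    marginals with the same weight scheme the empirical estimator uses.
    Returns None when chance agreement is degenerate (p_e = 1).
    """
    labels = list(prevalence)
    pi = np.array([prevalence[k] for k in labels])
    A = _kernel_matrix(kernel_a, labels)
    B = _kernel_matrix(kernel_b, labels)
    joint = np.einsum("t,ti,tj->ij", pi, A, B)
    marg_a = joint.sum(axis=1)
    marg_b = joint.sum(axis=0)
    e = np.outer(marg_a, marg_b)
    w = kappa_weight_matrix(labels, weighting, dictionary)
    expected_disagreement = float((w * e).sum())
    if expected_disagreement == 0.0:
        return None
    return 1.0 - float((w * joint).sum()) / expected_disagreement


def expected_missed_pct(
    miss_a: float,
    miss_b: float,
    spurious_a: float = 0.0,
    spurious_b: float = 0.0,
) -> float:
    """Expected missed-cell percentage for two independent annotators.

    Over the union of distinct cells either annotator marks: a true cell
    seen by both is matched, seen by exactly one is missed, seen by
    neither does not appear; spurious cells are assumed unmatched (valid
    when true cells are well separated and spurious density is low).
    """
    seen_both = (1 - miss_a) * (1 - miss_b)
    seen_one = miss_a * (1 - miss_b) + miss_b * (1 - miss_a)
    total = seen_both + seen_one + spurious_a + spurious_b
    if total == 0:
        return 0.0
    return 100.0 * (seen_one + spurious_a + spurious_b) / total


def cell_points_and_labels(
    records: Sequence[AnnotationRecord],
) -> tuple[np.ndarray, list[str]]:
    """Extract cell point coordinates and labels from a record set."""
    pts, labels = [], []
    for rec in records:
        if rec.level == "cell" and rec.construct in ("point", "circle"):
            pts.append(rec.geometry[0])
            labels.append(rec.feature_name)
    return np.asarray(pts, dtype=float).reshape(-1, 2), labels


def render_thumbnail(
    truth: GroundTruth, downsample: float = 32.0
) -> np.ndarray:
    """Render a synthetic RGB thumbnail: pink tissue blobs on white.

    Region polygons (dilated) are painted in eosin-like pink over a
    white slide background, giving the tissue module a deterministic
    input whose tissue geometry is known exactly.
    """
    from shapely import contains_xy
    from shapely.ops import unary_union
    from shapely.geometry import Polygon, box as shapely_box

    w = int(np.ceil(truth.slide.width_px / downsample))
    h = int(np.ceil(truth.slide.height_px / downsample))
    shapes = [Polygon(r.geometry).buffer(3 * downsample)
              for r in truth.region_records()]
    shapes += [shapely_box(*r.box_corners()).buffer(downsample)
               for r in truth.box_records()]
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    if shapes:
        geom = unary_union(shapes)
        cx = (np.arange(w) + 0.5) * downsample
        cy = (np.arange(h) + 0.5) * downsample
        gx, gy = np.meshgrid(cx, cy)
        inside = contains_xy(geom, gx.ravel(), gy.ravel()).reshape(h, w)
        img[inside] = (228, 130, 180)  # eosin-like pink
    return img
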
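# Methods

`annoqc` measures the quality of multi-annotator annotation sets on
whole-slide images (WSIs): region polygons and cell points drawn by
pathologists inside designated bounding boxes, governed by a project
data dictionary. This note records the models, conventions and
numerical choices behind each component.

## Annotation model and coordinates

All geometry lives in 0-based base-resolution pixel coordinates, origin
top-left, x rightward, y downward — the raster convention of WSI tiles.
Polygon rings are stored unclosed; closure is implicit, and only the
GeoJSON exporter writes the explicitly closed rings RFC 7946 requires.
Circles are stored as centre + radius and buffered to 64-gon
approximations the moment they enter an areal computation (at 64
segments the area deficit versus a true disc is ~0.16%, far below any
tolerance used here).

Self-intersecting polygons are **rejected at load** with a
`SELF_INTERSECTION` issue rather than auto-repaired: repair (e.g.
`buffer(0)`) silently changes areas, which would corrupt every
downstream area-based statistic, most visibly the Jaccard index.
Validation is pure — it emits issues and never mutates records — and
every issue carries the slide id, an ISO 8601 UTC timestamp, and a rule
id from a fixed documented catalogue, so issue logs are machine-
triageable.

Label coarsening (`merge_labels`) follows `merge_parent` links to their
terminal root. This is what makes the operation idempotent for chains
deeper than one link, and it is the mechanism behind "with / without
tumour-cell categorisation" analyses: the nuclear pleomorphism grades
NP1/NP2/NP3 merge into a single tumour-cell class.

## Region agreement: Jaccard similarity

For a label L on one slide, each annotator's polygons are unioned
(overlaps within one annotator count once) and

JSI(A, B) = area(U_A ∩ U_B) / area(U_A ∪ U_B).

All clipping is exact polygon geometry (GEOS via shapely), never
rasterisation, so JSI is resolution-independent; the rasterisation
path (`raster_jaccard`, counting grid-cell centres at a configurable
pitch) exists purely as an independent test oracle. Conventions the
index itself leaves undefined: empty-vs-empty is 1.0 (two annotators
who both drew nothing agree), empty-vs-nonempty is 0.0. Per-polygon
JSI is exposed (`polygon_jaccard`) but per-label-union is the default
unit of analysis. Areas are converted to mm² by area · (mpp/1000)².

## Cell agreement: matching, breakdown, kappa

Two point annotations denote the same cell when they lie within a
**physical** radius of 3 µm — 12 px at 0.25 µm/px (×40) — of each
other; `default_radius_px` scales this by the slide's mpp so the
criterion is resolution-invariant.

The correspondence is a **minimum-cost maximum-cardinality one-to-one
assignment** on the bipartite graph of within-radius pairs, solved with
the Hungarian algorithm (forbidden edges are priced above any feasible
total, which makes cardinality dominate cost). A greedy pairing would
depend on point order and break A↔B symmetry; the assignment is
deterministic, and exact symmetry under swapping the annotators —
including tie cases — is guaranteed by canonicalising the argument
order before solving and transposing the result.

Over the N distinct cells seen by either annotator (matched pairs plus
cells unmatched on each side): *agreed* = matched with equal labels,
*disagreed* = matched with different labels, *missed* = annotated by
one annotator only; the three percentages sum to 100.

The confusion matrix counts matched pairs only, rows annotator A,
columns annotator B, in dictionary declaration order (keeping ordinal
chains contiguous). Cells labelled "unknown" are excluded from the
matrix and from kappa by default — the label exists precisely to keep
uncertain calls out of training data — but remain in the
agreed/disagreed/missed breakdown; a switch re-includes them as their
own category.

Cohen's kappa is computed as κ = 1 − Σ w·p / Σ w·e with observed
proportions p, chance proportions e from the marginals, and a
disagreement-weight matrix w. With `none` weighting (w = 1 off the
diagonal) this is the familiar (p_o − p_e)/(1 − p_e). For `linear` /
`quadratic` weighting the scheme is **ordinal-within-chain**: two
labels in the same ordinal group (NP1..NP3) weigh |rank
difference|/(k−1), optionally squared; any disagreement across groups
or involving a non-ordinal label weighs 1. The weighting scheme behind
published weighted-kappa values is rarely stated, so it is selectable;
`linear` is the default. Degenerate cases (empty matrix, p_e = 1)
return not-applicable rather than a number. With more than two
annotators on a slide, all unordered pairs are evaluated; project
summaries take unweighted means of the percentage breakdowns over
slide-pairs (each pair counts once regardless of cell count, with a
pooled-over-cells alternative via the pooled confusion matrix, whose
kappa is computed on the element-wise sum).

## Per-slide QC metrics

**Completeness** compares observed counts of region-level boxes,
cell-level boxes and distinct annotators against the dictionary's
required counts; it is monotone (adding annotations can never flip
complete→incomplete).

**Exhaustiveness** of a region box is
100 · area(union(regions) ∩ box ∩ tissue) / area(box ∩ tissue).
Regions are clipped to the box first (spill-over cannot inflate the
numerator) and unioned (overlaps never double-count — the metric is
invariant to splitting one polygon into two covering the same area).
With a tissue mask, both numerator and denominator are evaluated on the
mask grid (pixel centres), bounding the error by one mask-pixel row;
without a mask the denominator falls back to the full box area and the
result carries a warning. A box with zero tissue reports
not-applicable. The flagging threshold defaults to 50% when the
dictionary does not set one, and is surfaced in the report. In the
pipeline, exhaustiveness is computed per (box, box's annotator), since
each annotator's obligation is to cover their own box.

**Diversity** is the number of distinct region labels present,
excluding the "unknown" escape labels (annotated tissue, but not a
type), bounded by the dictionary's region-label count.

## Tissue segmentation

The mandate is basic tissue-vs-background separation, not artefact
detection. Default: convert RGB to HSV, Otsu-threshold the saturation
channel (stained tissue is saturated; glass background is near-white
and unsaturated), guard with an absolute saturation floor of 0.04 so
uniform images behave sensibly, then morphological opening (radius 1),
small-object removal (< 16 mask px) and hole filling (< 64 mask px).
Masks are computed at thumbnail scale (default downsample 32, i.e. one
mask pixel per 32 base px) — tissue extent does not need cellular
resolution and this keeps whole-project runs interactive. A
user-supplied mask always overrides computation; masks round-trip as
single-channel PNG plus a JSON sidecar carrying downsample and origin.

## The simulator and its closed forms

Real multi-annotator WSI annotations are rarely shareable, so testing
is built on simulation. `generate_ground_truth` lays out non-
overlapping boxes on a slide (default 4096×4096 px at 0.25 µm/px),
fills region boxes with star-shaped simple polygons (strictly
increasing vertex angles guarantee simplicity) and cell boxes with
points placed by dart-throwing under a minimum pairwise separation of
24 px — twice the matching radius — so that truth-vs-truth matching is
provably perfect and matching ambiguity cannot contaminate recovery
tests (a crowded mode with zero separation exists to stress the
matcher). Cell labels are drawn from a prevalence over six classes
(defaults: NP1 0.20, NP2 0.15, NP3 0.05, TILs 0.20, stromal 0.25,
normal epithelial 0.15 — a tumour-rich breast H&E field).

`simulate_annotator` applies, independently per true cell: omission
with probability `miss_rate` (default study condition 0.3; roughly a
third of cells being missed by one of two annotators is the regime
reported for exhaustive box annotation), label substitution through a
per-true-label confusion kernel (default: 0.1 probability per adjacent
NP grade, the canonical hard distinction; non-tumour labels faithful),
and isotropic Gaussian position jitter (default σ 2 px — well under
the radius, so jitter alone neither unmatches nor mismatches). Spurious
cells arrive as Poisson(spurious_rate × n_true), uniform in the cell
boxes, labelled from prevalence. Region vertices are jittered and
rejection-resampled until the ring is simple. Everything is
reproducible from integer seeds.

Two annotators are **conditionally independent given the truth** — the
simplest model with closed forms, and a documented limitation (real
pathologists share training and systematic biases, which inflates
observed agreement relative to this model; passing recovery tests
therefore validates the estimators, not any claim about real-world
agreement levels). Under it:

- expected missed fraction over the union of distinct cells, for miss
  rates m_a, m_b and spurious rates s_a, s_b:
  (m_a(1−m_b) + m_b(1−m_a) + s_a + s_b) / (1 − m_a m_b + s_a + s_b);
  with one perfect annotator this reduces to m_b.
- expected kappa: joint matched-label distribution
  p(i,j) = Σ_t π_t A(t,i) B(t,j), kappa from p and its marginals with
  the same weight matrix the estimator uses
  (`analytic_expected_kappa`, cross-checked by Monte-Carlo in tests).

## Pipeline and reproducibility

`run_qc` stages: load → validate → completeness → exhaustiveness →
diversity → agreement → aggregate. A failure on one slide or pair is
logged as a `STAGE_FAILURE` issue and the run continues. In
reproducible mode every timestamp (report generation and issue logging)
is pinned from the config and JSON is written with sorted keys, so
identical inputs give byte-identical `qc_report.json` — asserted in
tests by comparing raw bytes of two runs. Reports are emitted as JSON
plus CSV tables (per-slide metrics, per-label counts/areas, JSI table,
one confusion matrix per pair, issue log).

## Problem sizes and tolerances

Test and verification workloads are sized for a single CPU: geometry
versus the rasterisation oracle on 100 random polygon pairs at 0.05 px
grid (tolerance 0.01 — twice the worst deviation typically observed);
matching versus brute-force enumeration on 500 instances with ≤ 6
points per side; kappa versus an independent direct-formula
implementation on 1,000 random matrices at 1e-12; miss-rate recovery on
2,000 cells (±2 percentage points, ≈ 3σ of the binomial); kappa
recovery on 5,000 kernel-drawn matched cells over 10 seeds (±0.03);
pipeline determinism on a 3-slide, 2-annotator simulated project. The
whole suite runs in well under a minute.

## Known limitations

- Conditional independence of simulated annotators (above).
- The simulator does not model tissue texture, nucleus appearance, or
  spatially correlated errors (e.g. a whole region systematically
  mislabelled); spurious cells can in principle fall within the radius
  of a real unmatched cell, which the closed-form missed expectation
  ignores (negligible at the default separation and spurious rates).
- Tissue segmentation is deliberately basic; pen marks, blur and
  coverslip artefacts are the province of dedicated image-QC tools and
  are out of scope.
- Chance-corrected agreement for > 2 raters (Fleiss-style) is not
  implemented; multi-annotator slides are handled pairwise.
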
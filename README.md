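# annoqc — annotation quality control for whole-slide images

Large computational-pathology projects depend on region and cell
annotations drawn by multiple pathologists on whole-slide images
(WSIs). Annotation sets of that scale need the same quality control as
the images themselves: are the annotations *complete* (the protocol's
required boxes, by the required number of annotators), *exhaustive*
(what fraction of the tissue inside a designated box is actually
covered), *diverse* (how many region types were annotated), and do the
annotators *agree*? `annoqc` implements that QC as a library and CLI:
a data-dictionary-driven annotation model with validation and issue
logging, the four QC metrics, pairwise inter-annotator agreement, and
a multi-annotator simulator that makes every metric testable with no
external dataset.

## The statistics at the core

**Region agreement** is the Jaccard similarity index of two annotators'
per-label polygon unions, computed by exact polygon clipping:

> JSI = area(U_A ∩ U_B) / area(U_A ∪ U_B)

**Cell agreement** first matches the two annotators' point annotations:
two points may denote the same cell when they lie within a physical
radius of 3 µm (12 px at 0.25 µm/px, ×40). The matching is a
minimum-cost maximum-cardinality assignment — globally optimal,
deterministic and symmetric in the annotators. Matched and unmatched
cells give the agreed / disagreed / missed breakdown, a label-by-label
confusion matrix, and Cohen's kappa

> κ = 1 − Σᵢⱼ wᵢⱼ pᵢⱼ / Σᵢⱼ wᵢⱼ eᵢⱼ

with weights wᵢⱼ from ordinal distance within label chains (nuclear
pleomorphism NP1 < NP2 < NP3), so adjacent-grade disagreements are
penalised less than grade-skipping ones. Coarsened analyses (tumour
grades merged to a single class) come from the dictionary's
`merge_parent` links.

**Exhaustiveness** of a region box is the percentage of its *tissue*
area covered by the union of region annotations (overlaps counted
once); tissue is separated from slide background by Otsu thresholding
on the HSV saturation channel of a thumbnail.

## Worked example

Simulate a slide with known ground truth, two stochastic "pathologists"
(each missing 30% of cells, confusing adjacent NP grades with
probability 0.1, jittering positions by σ = 2 px), and measure their
agreement:

```python
import annoqc as aq
from annoqc.simulate import cell_points_and_labels

truth = aq.generate_ground_truth(
    aq.LayoutParams(cells_per_box=300, box_size_px=1600), seed=7)
kernel = aq.default_confusion_kernel(adjacent_np=0.1)
rec_a, rec_b = (
    aq.simulate_annotator(truth, aq.AnnotatorProfile(
        f"pathologist-{k}", miss_rate=0.3, confusion_kernel=kernel,
        position_jitter_sigma=2.0, boundary_jitter_sigma=6.0, seed=10 + k))
    for k in (1, 2))

radius = aq.default_radius_px(truth.slide)          # 12.0 px at 0.25 um/px
pa, la = cell_points_and_labels(rec_a)
pb, lb = cell_points_and_labels(rec_b)
matching = aq.match_points(pa, pb, radius)
bd = aq.cell_agreement(matching, la, lb)
cm = aq.confusion(matching, la, lb, truth.dictionary)
print(bd.agreed_pct, bd.disagreed_pct, bd.missed_pct)
print(aq.cohens_kappa(cm, "linear", truth.dictionary))
```

Output of the session this README was written from:

```
matching radius: 12.0 px at 0.25 um/px
cells: 150 matched, agreed 50.2%  disagreed 5.2%  missed 44.6%
weighted kappa (NP graded):   0.93
weighted kappa (grades merged): 1.00
region tumour                     JSI 0.95  union 0.0212 mm2
region stroma                     JSI 0.96  union 0.0239 mm2
```

Reading: with both annotators missing 30% of cells independently,
~45% of the distinct cells end up seen by only one of them (the
closed-form expectation is 2·0.3·0.7/(1−0.09) ≈ 46%), and almost all
label disagreement sits on adjacent pleomorphism grades — so the
ordinal-weighted kappa is high, and merging the grades into one tumour
class removes the disagreement entirely. The per-label region JSI is
near 1 because boundary jitter of a few pixels barely moves polygon
unions of this size.

The same analysis runs from the shell over a project directory:

```sh
annoqc simulate --out project/ --slides 3 --annotators 2 --seed 1
annoqc qc project/sim-*.json --dictionary project/dictionary.json \
    --slides project/slides.json --out report/ --reproducible
```

producing `report/qc_report.json`, per-slide and per-label CSV tables,
per-pair confusion matrices and the issue log.

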
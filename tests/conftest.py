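import numpy as np
import pytest

from annoqc import (
    AnnotationRecord,
    DataDictionary,
    Label,
    SlideContext,
    default_breast_dictionary,
)


@pytest.fixture
def breast_dictionary() -> DataDictionary:
    return default_breast_dictionary()


@pytest.fixture
def slide() -> SlideContext:
    return SlideContext(
        slide_id="s1", microns_per_pixel=0.25, width_px=4096, height_px=4096
    )


@pytest.fixture
def small_dictionary() -> DataDictionary:
    """Minimal dictionary: one region label, one box label, two cell labels."""
    return DataDictionary(
        labels=[
            Label("region_box", "region"),
            Label("cell_box", "cell"),
            Label("tumour", "region"),
            Label("stroma", "region"),
            Label("TILs", "cell"),
            Label("tumour_cell", "cell"),
        ],
        allowed_constructs={
            "region_box": ["bounding_box"],
            "cell_box": ["bounding_box"],
            "tumour": ["polygon"],
            "stroma": ["polygon"],
            "TILs": ["point", "circle"],
            "tumour_cell": ["point", "circle"],
        },
        required_region_boxes=2,
        required_cell_boxes=1,
        required_annotators=2,
    )


def make_record(
    ann_id="a-1",
    slide_id="s1",
    annotator="p1",
    level="region",
    construct="polygon",
    feature="tumour",
    geometry=((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)),
    **kw,
):
    return AnnotationRecord(
        annotation_id=ann_id,
        slide_id=slide_id,
        annotator_id=annotator,
        stain_type="H&E",
        level=level,
        construct=construct,
        feature_name=feature,
        geometry=[tuple(p) for p in geometry],
        created_at="2024-01-01T00:00:00Z",
        **kw,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_simple_polygon(rng: np.random.Generator, n=8, centre=(5.0, 5.0),
                          radius=4.0):
    """Star-shaped polygon: strictly increasing angles guarantee a simple
    ring (one vertex per angular sector)."""
    angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.1, 0.9, n)) / n
    radii = rng.uniform(0.3, 1.0, n) * radius
    return [
        (float(centre[0] + r * np.cos(t)), float(centre[1] + r * np.sin(t)))
        for r, t in zip(radii, angles)
    ]
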
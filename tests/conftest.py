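import numpy as np
import pytest

from angioqca.degrade import DegradationSpec
from angioqca.masks import CORONARY, SegmentationMask
from angioqca.phantom import (
    CatheterSpec,
    StenosisSpec,
    VesselTreeSpec,
    generate_phantom,
    sample_tree_and_stenosis,
)


def horizontal_bar_mask(width_px: int, size: int = 64, center_row: float | None = None,
                        spacing: float = 0.2) -> SegmentationMask:
    """A horizontal coronary-class bar of exact integer-quantised width:
    rows whose centers lie within width/2 of the bar center."""
    center_row = size / 2 if center_row is None else center_row
    labels = np.zeros((size, size), dtype=np.uint8)
    rows = np.arange(size)
    labels[np.abs(rows - center_row) <= width_px / 2, :] = CORONARY
    return SegmentationMask(labels, spacing)


def straight_tree(canvas: int = 192, diameter_mm: float = 2.5, spacing: float = 0.2,
                  taper: float = 0.0, french: int = 6) -> VesselTreeSpec:
    """A straight horizontal vessel through the canvas middle with a
    catheter entering from the left edge."""
    mid = canvas / 2
    return VesselTreeSpec(
        canvas_size=(canvas, canvas),
        pixel_spacing=spacing,
        main_centerline=((mid, 25.0), (mid, canvas - 25.0)),
        baseline_diameter=diameter_mm,
        taper_rate=taper,
        branches=(),
        catheter=CatheterSpec(
            french_size=french,
            control_points=((canvas - 20.0, 25.0), (mid + 30.0, 25.0), (mid, 25.0)),
            tip_position=(mid, 25.0),
        ),
    )


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight untapered vessel, 60% stenosis, no degradation."""
    tree = straight_tree(diameter_mm=2.5, taper=0.0)
    stenosis = StenosisSpec(arc_position=14.0, severity=0.6, length=6.0)
    return generate_phantom(tree, stenosis, DegradationSpec(), seed=0)


@pytest.fixture(scope="session")
def random_phantom():
    """One representative randomly sampled phantom (256 px canvas)."""
    rng = np.random.default_rng(7)
    tree, stenosis = sample_tree_and_stenosis(rng, canvas_size=(256, 256))
    return generate_phantom(tree, stenosis, DegradationSpec(), seed=7)
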
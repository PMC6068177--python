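import numpy as np
import pytest

from corneavasc import (
    GrowthParams,
    ModalityRenderConfig,
    RegionOfInterest,
    VesselSegment,
    VesselTree,
    generate_tree,
    render_modality,
)


@pytest.fixture
def full_roi():
    return RegionOfInterest.full_frame((304, 304))


@pytest.fixture
def tree():
    return generate_tree(7)


@pytest.fixture
def tiny_tree():
    """Hand-built three-segment tree with both caliber classes."""
    segs = [
        VesselSegment((1.5, 0.0), (1.5, 1.2), 0.05, 1, "large"),
        VesselSegment((1.5, 0.8), (2.2, 1.6), 0.03, 2, "large"),
        VesselSegment((1.5, 1.0), (0.8, 1.8), 0.012, 3, "small"),
    ]
    return VesselTree(segments=segs, field_width_mm=3.0, rng_seed=0)


@pytest.fixture
def clean_octa(tree):
    return render_modality(tree, 6, ModalityRenderConfig.clean("OCTA"), noise_seed=11)
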
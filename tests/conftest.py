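import numpy as np
import pytest
from scipy import ndimage as ndi

import fishsizer as fs

# Frozen seed base for the synthetic accuracy sweep; the sweep is shared by
# the segmentation-overlap, parameter-recovery, and accuracy tests.
SWEEP_SEED_BASE = 1000
SWEEP_N = 100

#: Down-scaled generator ranges for fast unit tests that only need a valid
#: larva image, not measurement-grade accuracy.
SMALL_RANGES = {
    "canvas": (240, 320),
    "span": (140.0, 190.0),
    "half_depth_max": (14.0, 22.0),
    "rotation_deg": (-15.0, 15.0),
}


@pytest.fixture(scope="session")
def accuracy_sweep():
    """Segment + measure 100 seeded synthetic larvae at default parameters.

    Returns one row per image with relative length/depth errors against the
    generator's ground truth, the mask/ground-truth Jaccard overlap, and
    head-side agreement.
    """
    rows = []
    for i in range(SWEEP_N):
        spec = fs.make_spec(SWEEP_SEED_BASE + i)
        image, truth = fs.render(spec)
        mask = fs.segment_larva(image)
        result = fs.measure(mask)
        inter = int((mask.pixels & truth.body_raster).sum())
        union = int((mask.pixels | truth.body_raster).sum())
        _, n_comp = ndi.label(mask.pixels, structure=np.ones((3, 3)))
        border_free = not (
            mask.pixels[0, :].any()
            or mask.pixels[-1, :].any()
            or mask.pixels[:, 0].any()
            or mask.pixels[:, -1].any()
        )
        rows.append(
            {
                "rel_length": result.length_px / truth.length_px - 1.0,
                "rel_depth": result.depth_px / truth.depth_at(50.0) - 1.0,
                "jaccard": inter / union,
                "head_true": truth.head_side,
                "head_est": result.head_side,
                "n_components": n_comp,
                "border_free": border_free,
            }
        )
    return rows


@pytest.fixture()
def small_larva():
    """One small rendered larva (image, truth) for fast pipeline tests."""
    spec = fs.make_spec(7, SMALL_RANGES)
    return fs.render(spec)
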
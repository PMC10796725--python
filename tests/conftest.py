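import numpy as np
import pytest

from endograin import morphometry as M
from endograin.tables import load_table3, load_table4


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture
def labels_from_mask():
    """Build a SegmentationLabels with one instance per connected region."""

    def _build(mask: np.ndarray, split: bool = False) -> M.SegmentationLabels:
        from skimage.measure import label as cc_label

        mask = mask.astype(bool)
        return M.SegmentationLabels(
            granule_labels=cc_label(mask, connectivity=1),
            pore_mask=~mask,
            shadow_mask=np.zeros_like(mask),
            background_mask=np.zeros_like(mask),
        )

    return _build
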
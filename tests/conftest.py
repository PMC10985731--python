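import numpy as np
import pytest

from spheroscore.segmentation import InstanceMask, SegmentationResult


def truth_segmentation(truth) -> SegmentationResult:
    """Wrap ground-truth masks as a SegmentationResult for scoring."""
    instances = [InstanceMask(mask=m, label=i + 1)
                 for i, m in enumerate(truth.instance_masks)]
    return SegmentationResult(instances=instances, backend_name="truth",
                              params_digest="truth")


@pytest.fixture
def truth_seg():
    return truth_segmentation


@pytest.fixture
def flat_image():
    """Constant 200-intensity standardized frame."""
    from spheroscore.io import GrayImage
    return GrayImage(pixels=np.full((1024, 1024), 200, dtype=np.uint8))
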
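import numpy as np
import pytest

from bbyolo.voc import AnnotatedImage, BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_annotation(rng, width=200, height=160, n_boxes=5, image_id="img"):
    boxes = []
    for _ in range(n_boxes):
        x0 = rng.uniform(0, width - 12)
        y0 = rng.uniform(0, height - 12)
        w = rng.uniform(4, min(60, width - x0))
        h = rng.uniform(4, min(60, height - y0))
        boxes.append(BoundingBox(x0, y0, x0 + w, y0 + h, int(rng.integers(3))))
    return AnnotatedImage(image_id, width, height, boxes)
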
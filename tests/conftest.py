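import numpy as np
import pytest

from blindval import (AnnotationCatalog, BinaryMask, CohortConfig,
                      DEFAULT_SCHEME, ValidatorBehavior, build_schedule,
                      simulate_validator)
from blindval.simulate import gen_masks


def random_mask(rng, image_id="img", source_id="s", shape=(24, 24), density=0.3):
    data = rng.random(shape) < density
    return BinaryMask(image_id=image_id, source_id=source_id, data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    """4 images x 2 sources with tiny in-memory masks."""
    rng = np.random.default_rng(7)
    images = tuple(f"im{i}" for i in range(4))
    sources = ("L1", "L2")
    masks = {
        (i, s): random_mask(rng, image_id=i, source_id=s, shape=(12, 12))
        for i in images for s in sources
    }
    return AnnotationCatalog(images=images, sources=sources, masks=masks)


@pytest.fixture
def synthetic_run():
    """A complete small blinded run: catalog, plan, provenance, log."""
    config = CohortConfig(n_images=25, width=48, height=48, seed=42,
                          duplicates={"L1": 6, "L2": 6, "model": 6})
    catalog = gen_masks(config)
    plan, prov = build_schedule(catalog, config.duplicates, seed=config.seed)
    behavior = ValidatorBehavior(seed=42, session_plan=[(len(plan), 0.0)])
    log = simulate_validator(plan, prov, behavior, DEFAULT_SCHEME)
    return catalog, plan, prov, log
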
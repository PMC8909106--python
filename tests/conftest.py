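from __future__ import annotations

import numpy as np
import pytest

from lbcscreen.slide_io import NEOPLASTIC, NILM, Slide
from lbcscreen.synthetic import SyntheticSlideConfig, generate_slide


@pytest.fixture(scope="session")
def desk_config() -> SyntheticSlideConfig:
    """Reduced-scale study conditions: 512 px slides, 128 px tiles."""
    return SyntheticSlideConfig.desk_scale()


@pytest.fixture(scope="session")
def neoplastic_slide(desk_config):
    """One deterministic neoplastic synthetic slide with annotations."""
    from dataclasses import replace
    cfg = replace(desk_config, seed=11)
    return generate_slide(cfg, slide_id="neo")


@pytest.fixture(scope="session")
def nilm_slide(desk_config):
    from dataclasses import replace
    cfg = replace(desk_config, seed=12, neoplastic_fraction_of_cells=0.0)
    return generate_slide(cfg, slide_id="nilm")


@pytest.fixture()
def solid_red_slide() -> Slide:
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    img[..., 0] = 255
    return Slide.from_array(img, "red")


@pytest.fixture(scope="session")
def tiny_cohorts(tmp_path_factory, desk_config):
    """Small train/val cohort directories for training-loop tests."""
    from lbcscreen.synthetic import generate_cohort

    root = tmp_path_factory.mktemp("cohorts")
    generate_cohort(root / "train", 6, 0.5, desk_config, seed=3,
                    split="train")
    generate_cohort(root / "val", 4, 0.5, desk_config, seed=103, split="val")
    return root
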
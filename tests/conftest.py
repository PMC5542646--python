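"""Shared fixtures.

Unit tests run the pipeline on small images with a reduced working grid and
short hash keys to stay fast; the acceptance suite (test_acceptance.py) uses
the default operating point and builds its own larger fixtures.
"""

import numpy as np
import pytest

from salret.config import PipelineConfig
from salret.index import build_index
from salret.synthetic import SyntheticSpec, generate_dataset


def fast_config(**overrides) -> PipelineConfig:
    base = dict(working_side=16, bits=32, rho=24, t=6, seed=5)
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    spec = SyntheticSpec(
        n_categories=4,
        images_per_category=6,
        size_range=(48, 80),
        seed=123,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_index(small_dataset):
    return build_index([d.image for d in small_dataset], fast_config())
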
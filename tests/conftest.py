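import numpy as np
import pytest

from wtseg.synthetic import CohortConfig, generate_cases
from wtseg.taxonomy import build_default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return build_default_taxonomy()


@pytest.fixture(scope="session")
def small_cohort(taxonomy):
    """A small in-memory cohort shared by training/inference tests."""
    cfg = CohortConfig(
        n_cases=6, image_size=96, base_spacing=0.5, regions_per_case=12,
        coverage=0.8, seed=7,
    )
    images, annset = generate_cases(cfg, taxonomy=taxonomy)
    return cfg, images, annset


def random_simplex(rng, shape, k):
    """Random probability field on the simplex."""
    v = rng.gamma(1.0, size=(*shape, k))
    return v / v.sum(axis=-1, keepdims=True)
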
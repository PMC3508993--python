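import numpy as np
import pytest

from conetop import (
    make_density_profile,
    render_montage,
    sample_mosaic,
)
from conetop.pipeline import analyze_mosaic


def uniform_truth(density, seed=0, radius=0.15, exclusion=1.0):
    """Small uniform-density disc mosaic, big enough to carry one field."""
    prof = make_density_profile(
        "uniform", d_max=float(density), d_min=float(density), retina_radius=radius
    )
    return sample_mosaic(prof, seed=seed, exclusion_radius=exclusion)


@pytest.fixture(scope="session")
def st_truth():
    return sample_mosaic(make_density_profile("rd10_st"), seed=1)


@pytest.fixture(scope="session")
def st_montage(st_truth):
    return render_montage(st_truth)


@pytest.fixture(scope="session")
def st_result(st_truth):
    """Truth-count pipeline run on the standard-housing mosaic."""
    return analyze_mosaic(st_truth, count_from_truth=True)
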
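import numpy as np
import pytest
from hypothesis import settings

from vinomics import FeatureMatrix, Platform, SampleDesign
from vinomics.simulate import _design

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def fb_design() -> list[SampleDesign]:
    return _design("FB")


@pytest.fixture
def icvv_design() -> list[SampleDesign]:
    return _design("ICVV")


def make_matrix(
    values,
    platform=Platform.NMR,
    sample_ids=None,
    metabolite_ids=None,
    mask=None,
    scale="raw",
) -> FeatureMatrix:
    """Small helper: FeatureMatrix from a samples x metabolites array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if metabolite_ids is None:
        metabolite_ids = [f"met{j}" for j in range(m)]
    if mask is None:
        mask = ~np.isfinite(values)
    return FeatureMatrix(
        platform=platform,
        sample_ids=sample_ids,
        metabolite_ids=metabolite_ids,
        values=values,
        missing_mask=np.asarray(mask, dtype=bool),
        scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
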
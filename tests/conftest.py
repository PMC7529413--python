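"""Shared fixtures: synthetic study-condition fields and blob movies."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stgranger import (
    InferenceConfig,
    SyntheticFieldSpec,
    SyntheticMovieSpec,
    causality_maps,
    central_region,
    ellipse_mask,
    generate_blob_movie,
    generate_var_fields,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=list(HealthCheck)
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_fields():
    """Synthetic fields at the study conditions: 32x32 elliptical mask,
    T=166 at 0.36 s, AR(1) a=0.5, unit innovations, flow->nnd coupling
    c=0.5 at lag 3 injected in a 200-pixel interior region."""
    mask = ellipse_mask((32, 32))
    region = central_region(mask, 200)
    spec = SyntheticFieldSpec(coupling_coeff=0.5, causal_region=region, seed=1)
    stacks, gt = generate_var_fields(spec)
    return spec, stacks, gt


@pytest.fixture(scope="session")
def study_maps(study_fields):
    """All six directed causality maps for the study-condition fields."""
    _, stacks, _ = study_fields
    return causality_maps(stacks, InferenceConfig())


@pytest.fixture(scope="session")
def shifted_fields():
    """Study-condition fields with the coupling placed in a high-flow,
    low-NND region (mean shifts +1/-1), plus the detected flow->nnd map."""
    mask = ellipse_mask((32, 32))
    region = central_region(mask, 200)
    spec = SyntheticFieldSpec(
        coupling_coeff=0.5,
        causal_region=region,
        region_mean_shift={"flow": 1.0, "nnd": -1.0},
        seed=1,
    )
    stacks, gt = generate_var_fields(spec)
    fmap = causality_maps(stacks, InferenceConfig(), pairs=[("flow", "nnd")])[("flow", "nnd")]
    return spec, stacks, gt, fmap


@pytest.fixture(scope="session")
def drift_movie():
    """50-blob movie with heterogeneous blob sizes and per-blob drift."""
    rng = np.random.default_rng(7)
    drift = rng.uniform(-0.7, 0.7, size=(50, 2))
    spec = SyntheticMovieSpec(
        n_blobs=50,
        n_frames=6,
        drift_px=drift,
        blob_sigma_px=(1.5, 3.0),
        margin_px=14,
        min_separation_px=10,
        seed=7,
    )
    movie, gt = generate_blob_movie(spec)
    return spec, movie, gt
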
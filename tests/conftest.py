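from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cortexbench as cb
from cortexbench.projection import (
    ProjectionGrid,
    build_projection,
    project_features,
    stack_images,
    znormalize_images,
)
from cortexbench.evaluation import assemble_feature_vector

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mesh2() -> cb.SphereMesh:
    return cb.make_icosphere(2)


@pytest.fixture(scope="session")
def mesh3() -> cb.SphereMesh:
    return cb.make_icosphere(3)


@pytest.fixture(scope="session")
def mesh4() -> cb.SphereMesh:
    return cb.make_icosphere(4)


def toy_cohort(n_sites: int = 4, n_per_site: int = 15, seed: int = 0,
               case_prob: float = 0.5) -> pd.DataFrame:
    """Small hand-rolled cohort table for splitting/normative tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        for j in range(n_per_site):
            rows.append({
                "subject_id": f"s{i}_{j:03d}",
                "site": f"site{i}",
                "age": float(np.maximum(rng.normal(30 + 5 * i, 8), 10)),
                "sex": int(rng.random() < 0.5),
                "dx": int(rng.random() < case_prob),
            })
    return pd.DataFrame(rows)


def render_feature_matrix(cohort, feats, mesh, height=64, width=64,
                          method="equal_area", modalities=("thickness",),
                          hemispheres=("lh", "rh")):
    """Project generated vertex features to the flattened normalized pixel matrix."""
    grid = ProjectionGrid(height, width, method)
    planes, masks = {}, {}
    for hemi in hemispheres:
        pmap = build_projection(mesh, grid)
        for mod in modalities:
            label = f"{mod}_{hemi}"
            planes[label] = project_features(pmap, feats[(mod, hemi)].values)
            masks[label] = pmap.valid
    stack = znormalize_images(stack_images(planes, masks))
    return assemble_feature_vector(stack)
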
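"""Shared fixtures: small phantoms and fitted component sets.

Expensive fits are session-scoped so the recovery, compression and probe
tests share one phantom and one sparse-filtering fit.
"""

import numpy as np
import pytest

import voxsparse as vs
from voxsparse.phantom import Box, PhantomSpec


@pytest.fixture(scope="session")
def tiny_spec():
    """Two disjoint boxes in a 10^3 grid with a labeled background."""
    return PhantomSpec(
        grid_dims=(10, 10, 10),
        regions=(Box(2, (1, 1, 1), (3, 3, 3)), Box(3, (6, 6, 6), (3, 3, 3))),
        n_genes=60, markers_per_region=6, marker_amplitude=1.0,
        noise_sd=0.3, background_fraction=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return vs.make_phantom(tiny_spec)


@pytest.fixture(scope="session")
def study_phantom():
    """The reference study conditions: eight 10^3 regions tiling 20^3,
    1000 genes, 30 markers per region, noise SD 0.5."""
    spec = vs.default_phantom_spec(seed=1)
    return vs.make_phantom(spec)


@pytest.fixture(scope="session")
def study_fit(study_phantom):
    """One sparse-filtering fit (K=8) on the study phantom, shared by the
    recovery / metrics / acceptance tests."""
    expr, ann, mm = study_phantom
    return vs.sparse_filter(expr, 8, max_iter=300, seed=0)


@pytest.fixture(scope="session")
def study_truth(study_phantom):
    expr, ann, _ = study_phantom
    return ann.labels_at(expr.voxel_coords)


def make_expression(values, seed_coords=True):
    """Wrap a plain array as an ExpressionMatrix with dummy coordinates."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int),
                              np.zeros(n, int)])
    genes = [f"g{i:03d}" for i in range(values.shape[1])]
    return vs.ExpressionMatrix(values, coords, genes)
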
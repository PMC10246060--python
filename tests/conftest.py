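"""Shared fixtures: small synthetic heads, coils, and solved toy datasets."""

from __future__ import annotations

import numpy as np
import pytest

from tmsfield import coilmodel, fieldsolver, headmodel


@pytest.fixture(scope="session")
def homog_head():
    """Homogeneous 48^3 spherical head (the canonical solver-validation case)."""
    return headmodel.make_sphere_head(outer_radius_mm=56.0,
                                      shells=[(56.0, 0.33)],
                                      grid_shape=(48, 48, 48), voxel_mm=2.5)


@pytest.fixture(scope="session")
def shell_head():
    """Default 5-shell 48^3 spherical head."""
    return headmodel.make_sphere_head()


@pytest.fixture(scope="session")
def small_head():
    """Tiny 5-shell head for fast pipeline tests (24^3 at 4 mm)."""
    return headmodel.make_sphere_head(outer_radius_mm=40.0,
                                      grid_shape=(24, 24, 24), voxel_mm=4.0)


@pytest.fixture(scope="session")
def figure8():
    return coilmodel.make_figure8_coil()


@pytest.fixture(scope="session")
def tiny_dataset(small_head, figure8):
    """Eight solved ground-truth cases on the tiny head, 16^3 FOV."""
    cv, geom = small_head
    ps = coilmodel.sample_placements(geom, n_cases=8, n_directions=6, seed=11)
    return fieldsolver.make_dataset(geom, cv, figure8, ps,
                                    fov_shape=(16, 16, 16), tol=1e-7)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained surrogate for protocol/prediction plumbing tests."""
    from tmsfield import surrogate

    cfg = surrogate.SurrogateConfig(epochs=5, base_channels=4, seed=3)
    return surrogate.train_surrogate(tiny_dataset, cfg)


def random_rigid(rng: np.random.Generator, max_translation: float = 20.0):
    """A uniformly random proper rigid transform (for property tests)."""
    from tmsfield.geometry import RigidTransform

    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform.from_rotation_translation(q, t)
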
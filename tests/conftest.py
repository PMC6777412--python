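import numpy as np
import pytest
from scipy.integrate import dblquad

from deltarad.grids import RoiMask, VolumeGrid


def make_ellipsoid_mask(semi_axes, spacing=(1.0, 1.0, 1.0), pad=3) -> RoiMask:
    """Voxelized ellipsoid centered on its grid (centers-inside rule)."""
    semi_axes = np.asarray(semi_axes, float)
    sp = np.asarray(spacing, float)
    n = (2 * np.ceil(semi_axes / sp).astype(int) + 2 * pad + 1)
    idx = np.indices(n).astype(float)
    c = (n - 1) / 2
    x = (idx - c.reshape(3, 1, 1, 1)) * sp.reshape(3, 1, 1, 1)
    inside = ((x[0] / semi_axes[0]) ** 2 + (x[1] / semi_axes[1]) ** 2
              + (x[2] / semi_axes[2]) ** 2) <= 1.0
    return RoiMask(inside, tuple(spacing))


def make_ball_mask(radius, spacing=(1.0, 1.0, 1.0)) -> RoiMask:
    return make_ellipsoid_mask((radius, radius, radius), spacing)


def ellipsoid_surface_area(a, b, c) -> float:
    """Surface area of an ellipsoid by quadrature over its parametrization."""
    def integrand(v, u):
        return np.sin(v) * np.sqrt(
            (b * c * np.cos(u) * np.sin(v)) ** 2
            + (a * c * np.sin(u) * np.sin(v)) ** 2
            + (a * b * np.cos(v)) ** 2)
    val, _ = dblquad(integrand, 0, 2 * np.pi, 0, np.pi, epsabs=1e-8)
    return val


def volume_on(mask: RoiMask, values: np.ndarray, modality="CT") -> VolumeGrid:
    return VolumeGrid(values, mask.spacing, mask.origin, modality)


@pytest.fixture(scope="session")
def roundness_fixture():
    from deltarad.longitudinal import load_fixture_roundness
    return load_fixture_roundness()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny fully-filled synthetic cohort shared across tests."""
    from deltarad.synthetic import PhantomSpec, generate_cohort
    spec = PhantomSpec(n_patients=4, recurrence_fraction=0.5, seed=11,
                       ct_shape=(48, 48, 32), pet_shape=(14, 14, 32),
                       drop_mid_for=(3,))
    return generate_cohort(spec)
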
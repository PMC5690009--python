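import numpy as np
import pytest

import tg43qa as q


@pytest.fixture(scope="session")
def spec():
    return q.SyntheticAnisotropySpec()


@pytest.fixture(scope="session")
def dense_table(spec):
    return q.make_reference_anisotropy(spec)


@pytest.fixture(scope="session")
def vendor_table(dense_table):
    return q.subsample_vendor(dense_table)


@pytest.fixture(scope="session")
def source():
    return q.default_source()


@pytest.fixture(scope="session")
def radial_model():
    return q.make_radial_model("polynomial")


@pytest.fixture(scope="session")
def engine_pair(spec):
    """(reference, vendor) engines under the default study conditions."""
    return q.default_engines(spec)


@pytest.fixture(scope="session")
def flat_anisotropy():
    """Isotropic F == 1 on a small grid, engine (tip-at-0) convention."""
    radii = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
    angles = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0])
    return q.AnisotropyTable(
        radii=radii,
        angles=angles,
        values=np.ones((radii.size, angles.size)),
        provenance="flat",
        theta_zero="tip",
    )
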
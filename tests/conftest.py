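import numpy as np
import pytest

from basecraft import synthdata as sd


@pytest.fixture(scope="session")
def bundle():
    """Default idealized four-helix bundle."""
    return sd.build_bundle()


@pytest.fixture(scope="session")
def wide_bundle():
    """Bundle with a lumen wide enough to host the analogue."""
    return sd.build_bundle(sd.BundleSpec(helix_length=14, radius=8.5))


@pytest.fixture(scope="session")
def planted(wide_bundle):
    """One planted catalytic site: (structure, pose, ground truth)."""
    return sd.plant_catalytic_site(wide_bundle, ("B", 9), "ASP")


@pytest.fixture
def helix_backbone():
    """A single-residue backbone triplet for side-chain construction."""
    return {
        "N": np.zeros(3),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([1.996, 1.423, 0.0]),
        "O": np.array([1.246, 2.390, 0.0]),
    }


def random_rigid_transform(rng):
    """A uniformly random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t


def apply_rigid(structure, R, t):
    s = structure.copy()
    for model in s.models:
        for r in model:
            for a in r.atoms:
                a.pos = R @ a.pos + t
    return s
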
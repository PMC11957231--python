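import numpy as np
import pytest

from fluoropose.geometry import Intrinsics, RadiologicParams, pose_from_radiologic
from fluoropose.rendering import Volume3D


@pytest.fixture(scope="session")
def smooth_volume():
    """Sum of off-center 3D Gaussian blobs: smooth, asymmetric attenuation
    (no flat gradients in any pose direction), 32^3 at 4 mm."""
    n = 32
    idx = np.arange(n)
    c = (n - 1) / 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    blobs = [
        ((4, -3, 2), 5.0, 0.03),
        ((-6, 5, -4), 7.0, 0.02),
        ((2, 6, 6), 4.0, 0.025),
    ]
    v = np.zeros((n, n, n))
    for (dx, dy, dz), s, amp in blobs:
        v += amp * np.exp(
            -((X - c - dx) ** 2 + (Y - c - dy) ** 2 + (Z - c - dz) ** 2) / (2 * s**2)
        )
    return Volume3D.centered(v, 4.0)


@pytest.fixture(scope="session")
def detector64():
    return Intrinsics(sdd=1000.0, height=64, width=64, delx=3.0, dely=3.0)


@pytest.fixture(scope="session")
def frontal_pose():
    return pose_from_radiologic(RadiologicParams(), 700.0)


@pytest.fixture(scope="session")
def oblique_pose():
    return pose_from_radiologic(
        RadiologicParams(alpha=20.0, beta=10.0, gamma=5.0, bx=5.0, by=-20.0, bz=8.0),
        700.0,
    )
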
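import numpy as np
import pytest

from muellerpol import AcquisitionConfig, CalibrationResult


@pytest.fixture
def noiseless_acq() -> AcquisitionConfig:
    return AcquisitionConfig(noise_model="none", seed=0)


@pytest.fixture
def true_calibration(noiseless_acq) -> CalibrationResult:
    """A CalibrationResult carrying the simulator's exact instrument matrices."""
    return CalibrationResult(
        W=noiseless_acq.W_true.copy(), A=noiseless_acq.A_true.copy(), residual=0.0
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_state_matrices(rng: np.random.Generator):
    """Random well-conditioned physical (W, A): rotated tetrahedra of states."""
    from muellerpol.optics import tetrahedron_stokes

    states = tetrahedron_stokes()
    W = states.copy()
    W[:, 1:] = states[:, 1:] @ random_rotation(rng).T
    A = states.copy()
    A[:, 1:] = states[:, 1:] @ random_rotation(rng).T
    return W.T.copy(), A


def random_physical_mueller(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random physical Mueller matrices: depolarizer . retarder . diattenuator."""
    from muellerpol.mueller import _diattenuator_from_vector
    from muellerpol.synthetic import _retarder_batch

    delta = rng.uniform(0.0, 0.95, n)
    k = 1.0 - delta
    m_delta = np.zeros((n, 4, 4))
    m_delta[:, 0, 0] = 1.0
    for i in (1, 2, 3):
        m_delta[:, i, i] = k
    m_r = _retarder_batch(rng.uniform(0.0, 179.0, n), rng.uniform(0.0, 180.0, n))
    d = rng.uniform(0.0, 0.8, n)
    ax = np.deg2rad(rng.uniform(0.0, 180.0, n))
    dvec = d[:, None] * np.stack(
        [np.cos(2 * ax), np.sin(2 * ax), np.zeros(n)], axis=-1
    )
    return m_delta @ m_r @ _diattenuator_from_vector(dvec)
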
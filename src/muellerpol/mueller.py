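"""Per-pixel Mueller matrix reconstruction and Lu-Chipman polar decomposition.

The measured 16-frame intensity stack encodes, at every pixel, the 4x4
matrix B = A . M . W where W holds the four probing Stokes states (PSG)
as columns and A the four analyzer states (PSA) as rows.  Inverting the
calibrated A and W yields the sample Mueller matrix M, which is then
factored as M = M_delta . M_R . M_D (depolarizer, retarder, diattenuator).

Scalar maps derived from the factors:

* depolarization  Delta = 1 - (|a| + |b| + |c|) / 3,  a, b, c the
  eigenvalues of the 3x3 depolarizer block (0 = none, 1 = full);
* retardance      R = arccos(tr(M_R)/2 - 1)  in degrees (0 to 180);
* diattenuation   D = |(m01, m02, m03)| of the normalized matrix.

All decomposition arithmetic is vectorized over arbitrary leading axes so
a whole image decomposes in a handful of batched linalg calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityStack",
    "MuellerMap",
    "DecompositionResult",
    "reconstruct",
    "lu_chipman",
    "lu_chipman_batch",
    "decompose_map",
    "retarder_axis",
    "linear_retardance",
    "coherency_matrix",
    "physical_realizability",
]

#: Condition number above which a calibration matrix is considered singular.
COND_LIMIT = 1e8

#: Diattenuation magnitude at which the diattenuator factor is clamped to
#: keep its inverse finite (near-ideal polarizer).
D_CLAMP = 1.0 - 1e-6

_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class IntensityStack:
    """A 16-frame polarization-modulated acquisition.

    ``frames`` has shape (16, H, W); frame k holds the intensity measured
    with PSG state i = k // 4 and PSA state j = k % 4 (PSG-major order),
    i.e. element (j, i) of the per-pixel matrix B.
    """

    frames: np.ndarray
    frame_order: str = "psg-major"
    wavelength_nm: float = 550.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 16:
            raise ValueError(
                f"frames must have shape (16, H, W), got {self.frames.shape}"
            )
        if self.frame_order != "psg-major":
            raise ValueError(f"unsupported frame order {self.frame_order!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def b_matrices(self) -> np.ndarray:
        """Per-pixel B matrices, shape (H, W, 4, 4) with B[j, i] = frame 4i+j."""
        h, w = self.shape
        # frames index k = 4*i + j -> reshape to (i, j, H, W), transpose to B[j, i]
        b = self.frames.reshape(4, 4, h, w)
        return np.transpose(b, (2, 3, 1, 0))

    @classmethod
    def from_b_matrices(cls, b: np.ndarray, **kwargs) -> "IntensityStack":
        b = np.asarray(b, dtype=float)
        frames = np.transpose(b, (3, 2, 0, 1)).reshape(16, *b.shape[:2])
        return cls(frames=frames, **kwargs)


@dataclass
class MuellerMap:
    """Per-pixel normalized Mueller matrices with the unnormalized m11 image."""

    matrices: np.ndarray  # (H, W, 4, 4), element (0, 0) == 1 on valid pixels
    m11: np.ndarray  # (H, W) unnormalized first element
    wavelength_nm: float = 550.0
    mask: np.ndarray | None = None  # True where valid

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.m11 = np.asarray(self.m11, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.m11.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.m11.shape


@dataclass
class DecompositionResult:
    """Lu-Chipman factors and the scalar maps extracted from them."""

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    delta: np.ndarray
    retardance: np.ndarray  # degrees
    diattenuation: np.ndarray
    depol_eigs: np.ndarray  # (..., 3) eigenvalues of the depolarizer block
    mask: np.ndarray | None = None
    clamp_count: int = 0  # arccos arguments clipped into [-1, 1]
    d_clamp_count: int = 0  # near-ideal-polarizer pixels clamped at D_CLAMP


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct(stack: IntensityStack, cal) -> MuellerMap:
    """Invert B = A . M . W per pixel: M = A^-1 . B . W^-1.

    ``cal`` provides ``A`` and ``W`` either globally (4, 4) or per pixel
    (H, W, 4, 4).  Pixels where either matrix is near-singular (condition
    number above ``COND_LIMIT``) are masked invalid rather than raising.
    """
    b = stack.b_matrices()
    h, w = stack.shape
    A = np.asarray(cal.A, dtype=float)
    W = np.asarray(cal.W, dtype=float)
    if A.ndim == 2:
        A = np.broadcast_to(A, (h, w, 4, 4))
    if W.ndim == 2:
        W = np.broadcast_to(W, (h, w, 4, 4))

    mask = (np.linalg.cond(A) < COND_LIMIT) & (np.linalg.cond(W) < COND_LIMIT)
    A_inv = np.full((h, w, 4, 4), np.nan)
    W_inv = np.full((h, w, 4, 4), np.nan)
    if mask.any():
        A_inv[mask] = np.linalg.inv(A[mask])
        W_inv[mask] = np.linalg.inv(W[mask])

    M = A_inv @ b @ W_inv
    m11 = M[..., 0, 0].copy()
    mask = mask & (m11 > 0) & np.isfinite(m11)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = M / m11[..., None, None]
    return MuellerMap(
        matrices=normalized,
        m11=m11,
        wavelength_nm=stack.wavelength_nm,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Lu-Chipman polar decomposition


def _diattenuator_from_vector(dvec: np.ndarray) -> np.ndarray:
    """Canonical diattenuator M_D for D-vectors of shape (..., 3)."""
    d = np.linalg.norm(dvec, axis=-1)
    q = np.sqrt(np.clip(1.0 - d * d, 0.0, None))
    # unit axis; arbitrary (irrelevant) where D == 0
    safe = np.where(d > 0, d, 1.0)[..., None]
    dhat = dvec / safe
    eye3 = np.eye(3)
    outer = dhat[..., :, None] * dhat[..., None, :]
    m_small = q[..., None, None] * eye3 + (1.0 - q)[..., None, None] * outer
    out = np.zeros(dvec.shape[:-1] + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 0, 1:] = dvec
    out[..., 1:, 0] = dvec
    out[..., 1:, 1:] = m_small
    return out


def lu_chipman_batch(M: np.ndarray) -> DecompositionResult:
    """Lu-Chipman polar decomposition of normalized matrices, shape (..., 4, 4).

    Factors M = M_delta . M_R . M_D.  The diattenuator is built from the
    first-row D-vector; M' = M . M_D^-1 is split by singular value
    decomposition of its 3x3 block m' into a symmetric depolarizer block
    (the signed square root of m' m'^T, sign from det m') and a proper
    rotation (the retarder block).  The SVD route stays defined when m' is
    singular (full depolarization), where the retarder degenerates to the
    identity.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError(f"expected (..., 4, 4) matrices, got {M.shape}")

    dvec = M[..., 0, 1:4].copy()
    diatt = np.linalg.norm(dvec, axis=-1)
    over = diatt > D_CLAMP
    d_clamp_count = int(np.count_nonzero(over))
    if d_clamp_count:
        dvec = np.where(over[..., None], dvec * (D_CLAMP / diatt)[..., None], dvec)
        diatt = np.minimum(diatt, D_CLAMP)

    M_D = _diattenuator_from_vector(dvec)
    Mp = M @ np.linalg.inv(M_D)
    mprime = Mp[..., 1:, 1:]

    U, s, Vt = np.linalg.svd(mprime)
    sign = np.sign(np.linalg.det(U @ Vt))
    sign = np.where(sign == 0, 1.0, sign)
    m_R3 = sign[..., None, None] * (U @ Vt)
    m_delta3 = sign[..., None, None] * (U * s[..., None, :]) @ np.swapaxes(U, -1, -2)
    depol_eigs = sign[..., None] * s

    delta = 1.0 - np.abs(depol_eigs).sum(axis=-1) / 3.0

    batch = M.shape[:-2]
    M_R = np.zeros(batch + (4, 4))
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = m_R3
    M_delta = np.zeros(batch + (4, 4))
    M_delta[..., 0, 0] = 1.0
    M_delta[..., 1:, 0] = Mp[..., 1:, 0]
    M_delta[..., 1:, 1:] = m_delta3

    arg = np.trace(M_R, axis1=-2, axis2=-1) / 2.0 - 1.0
    clamp_count = int(np.count_nonzero((arg < -1.0) | (arg > 1.0)))
    retardance = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))

    return DecompositionResult(
        M_delta=M_delta,
        M_R=M_R,
        M_D=M_D,
        delta=delta,
        retardance=retardance,
        diattenuation=diatt,
        depol_eigs=depol_eigs,
        clamp_count=clamp_count,
        d_clamp_count=d_clamp_count,
    )


def lu_chipman(M: np.ndarray):
    """Decompose a single normalized 4x4 Mueller matrix.

    Returns ``(M_D, M_delta, M_R, diattenuation, delta, retardance)`` with
    the retardance in degrees.  Raises if element (0, 0) differs from 1.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got {M.shape}")
    if not np.isclose(M[0, 0], 1.0):
        raise ValueError("matrix must be normalized: element (0, 0) must be 1")
    r = lu_chipman_batch(M[None])
    return (
        r.M_D[0],
        r.M_delta[0],
        r.M_R[0],
        float(r.diattenuation[0]),
        float(r.delta[0]),
        float(r.retardance[0]),
    )


def decompose_map(mueller: MuellerMap) -> DecompositionResult:
    """Apply the Lu-Chipman decomposition independently at every valid pixel.

    Invalid pixels propagate through the mask; their scalar maps are NaN.
    """
    h, w = mueller.shape
    mask = mueller.mask.copy()
    out = DecompositionResult(
        M_delta=np.full((h, w, 4, 4), np.nan),
        M_R=np.full((h, w, 4, 4), np.nan),
        M_D=np.full((h, w, 4, 4), np.nan),
        delta=np.full((h, w), np.nan),
        retardance=np.full((h, w), np.nan),
        diattenuation=np.full((h, w), np.nan),
        depol_eigs=np.full((h, w, 3), np.nan),
        mask=mask,
    )
    if not mask.any():
        return out
    r = lu_chipman_batch(mueller.matrices[mask])
    out.M_delta[mask] = r.M_delta
    out.M_R[mask] = r.M_R
    out.M_D[mask] = r.M_D
    out.delta[mask] = r.delta
    out.retardance[mask] = r.retardance
    out.diattenuation[mask] = r.diattenuation
    out.depol_eigs[mask] = r.depol_eigs
    out.clamp_count = r.clamp_count
    out.d_clamp_count = r.d_clamp_count
    return out


# ---------------------------------------------------------------------------
# retarder parameter extraction


def retarder_axis(M_R: np.ndarray) -> np.ndarray:
    """Fast-axis azimuth (degrees in [0, 180)) of the retarder factor.

    Derived from the linear components of the retardance vector; undefined
    (returns NaN) where the total retardance is 0 or 180 degrees.
    """
    M_R = np.asarray(M_R, dtype=float)
    r = M_R[..., 1:, 1:]
    a1 = r[..., 2, 1] - r[..., 1, 2]
    a2 = r[..., 0, 2] - r[..., 2, 0]
    axis = 0.5 * np.degrees(np.arctan2(a2, a1)) % 180.0
    sin_r = np.hypot(a1, a2)
    with np.errstate(invalid="ignore"):
        return np.where(sin_r > 1e-12, axis, np.nan)


def linear_retardance(M_R: np.ndarray) -> np.ndarray:
    """Linear (in-plane) retardance in degrees from the retarder block.

    Distinct from the total retardance arccos(tr(M_R)/2 - 1): this drops
    any circular (optical-rotation) component.
    """
    M_R = np.asarray(M_R, dtype=float)
    r = M_R[..., 1:, 1:]
    arg = np.sqrt((r[..., 0, 0] + r[..., 1, 1]) ** 2 + (r[..., 1, 0] - r[..., 0, 1]) ** 2) - 1.0
    return np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# physical realizability (Cloude coherency criterion)


def coherency_matrix(M: np.ndarray) -> np.ndarray:
    """Hermitian 4x4 coherency matrix T of Mueller matrices (..., 4, 4).

    T = (1/4) sum_ij m_ij (sigma_i x sigma_j*), sigma the Pauli basis with
    the identity first.  tr T = m00; M is a convex mixture of deterministic
    (Jones) elements iff T is positive semidefinite.
    """
    M = np.asarray(M, dtype=float)
    T = 0.25 * np.einsum(
        "...ij,iab,jcd->...acbd", M, _PAULI, _PAULI.conj()
    ).reshape(M.shape[:-2] + (4, 4))
    return T


def physical_realizability(M: np.ndarray, tol: float = 1e-9):
    """Check whether M can arise from an ensemble of deterministic elements.

    Returns ``(is_physical, min_coherency_eig)`` where the eigenvalue is
    taken after normalizing T to unit trace; ``is_physical`` is True when
    the smallest eigenvalue is >= -tol.
    """
    T = coherency_matrix(M)
    tr = np.real(np.trace(T, axis1=-2, axis2=-1))
    eigs = np.linalg.eigvalsh(T / tr[..., None, None])
    min_eig = eigs[..., 0]
    if min_eig.ndim == 0:
        return bool(min_eig >= -tol), float(min_eig)
    return min_eig >= -tol, min_eig
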
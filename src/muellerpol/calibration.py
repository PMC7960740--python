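"""Eigenvalue calibration of the polarimeter's modulation and analysis matrices.

The eigenvalue calibration method (ECM) recovers the modulation matrix W
(columns = PSG probing Stokes states) and the analysis matrix A (rows =
PSA analyzer states) without any model of the instrument optics.  With a
polarimetrically neutral plate (M ~ identity) one measures B0 = A.W, then
B_i = A.M_i.W with each reference optic (polarizers, a waveplate)
inserted.  The matrices

    C_i = B0^-1 . B_i = W^-1 . M_i . W

are similar to the reference Mueller matrices, so their eigenvalues give
the references' transmittances and retardance directly, tolerating
imperfect components.  W is then the common null vector of the linear
maps X -> M_i X - X C_i: stacking their normal matrix

    K = sum_i H_i^T H_i,      H_i = I (x) M_i  -  C_i^T (x) I

(Kronecker products, column-major vectorization), W is the eigenvector of
K with the smallest eigenvalue.  Reference orientations are similarity
parameters invisible to the eigenvalues; they are refined by minimizing
the smallest eigenvalue of K.  Finally A = B0 . W^-1.

The scale ambiguity (K determines W up to a factor) is resolved by fixing
the intensity of the first PSG state: W[0, 0] = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .optics import linear_polarizer, linear_retarder

__all__ = [
    "ReferenceOptic",
    "CalibrationResult",
    "CalibrationError",
    "default_reference_set",
    "ecm_calibrate",
    "calibrate_field",
]

#: Required separation between the smallest and second-smallest eigenvalue
#: of K; a larger ratio means the reference set does not pin down W.
EIGENVALUE_GAP = 0.01

SCALE_CONVENTION = "W[0,0]=1"


class CalibrationError(RuntimeError):
    """Raised when the reference set cannot determine W."""


@dataclass(frozen=True)
class ReferenceOptic:
    """A calibration reference with well-known polarimetric properties."""

    kind: str  # "linear_polarizer" | "linear_retarder"
    orientation_deg: float
    retardance_deg: float | None = None  # retarder only
    transmittance: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_polarizer", "linear_retarder"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if not 0.0 <= self.orientation_deg < 180.0:
            raise ValueError("orientation must be in [0, 180)")
        if self.kind == "linear_retarder":
            if self.retardance_deg is None or not 0.0 < self.retardance_deg <= 180.0:
                raise ValueError("retarder needs retardance in (0, 180]")

    def mueller(self) -> np.ndarray:
        if self.kind == "linear_polarizer":
            return linear_polarizer(self.orientation_deg, self.transmittance)
        return self.transmittance * linear_retarder(
            self.retardance_deg, self.orientation_deg
        )


def default_reference_set() -> list[ReferenceOptic]:
    """The canonical well-conditioned trio: two polarizers and a waveplate."""
    return [
        ReferenceOptic("linear_polarizer", 0.0),
        ReferenceOptic("linear_polarizer", 90.0),
        ReferenceOptic("linear_retarder", 30.0, retardance_deg=109.0),
    ]


@dataclass
class CalibrationResult:
    """Recovered W and A with a least-squares diagnostic.

    ``residual`` is the ratio of the smallest to the second-smallest
    eigenvalue of K: near zero means the reference measurements are
    mutually consistent and W is sharply determined.
    """

    W: np.ndarray
    A: np.ndarray
    residual: float | np.ndarray
    scale_convention: str = SCALE_CONVENTION
    refined_refs: list = field(default_factory=list)
    mask: np.ndarray | None = None  # per-pixel validity (field calibrations)


# ---------------------------------------------------------------------------


def _refine_from_eigenvalues(ref: ReferenceOptic, C: np.ndarray) -> ReferenceOptic:
    """Re-estimate transmittance / retardance from the eigenvalues of C.

    C = W^-1 M W shares the eigenvalues of the reference matrix M: a
    polarizer has {tau, 0, 0, 0}; a retarder of transmittance tau and
    phase delta has {tau, tau, tau e^{+i delta}, tau e^{-i delta}}.
    """
    eigs = np.linalg.eigvals(C)
    if ref.kind == "linear_polarizer":
        tau = float(np.real(eigs[np.argmax(np.abs(eigs))]))
        return replace(ref, transmittance=tau)
    idx = np.argmax(np.imag(eigs))
    delta = float(np.degrees(np.abs(np.angle(eigs[idx]))))
    tau = float(np.mean(np.abs(eigs)))
    return replace(ref, transmittance=tau, retardance_deg=delta)


def _normal_matrix(ms: list[np.ndarray], cs: list[np.ndarray]) -> np.ndarray:
    eye = np.eye(4)
    K = np.zeros((16, 16))
    for M, C in zip(ms, cs):
        H = np.kron(eye, M) - np.kron(C.T, eye)
        K += H.T @ H
    return K


def _smallest_two(K: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    vals, vecs = np.linalg.eigh(K)
    return vecs[:, 0], float(vals[0]), float(vals[1]), float(vals[-1])


def ecm_calibrate(
    B0: np.ndarray,
    B_list: list[np.ndarray],
    refs: list[ReferenceOptic],
    refine_orientations: bool = True,
    orientation_window_deg: float = 5.0,
    gap_threshold: float = EIGENVALUE_GAP,
) -> CalibrationResult:
    """Recover W and A from one neutral-plate and >= 3 reference acquisitions.

    Parameters
    ----------
    B0 : (4, 4) intensity matrix of the neutral plate alone (M ~ I).
    B_list : one (4, 4) intensity matrix per reference optic.
    refs : nominal descriptions of the reference optics, in the same order.
    refine_orientations : also refine each reference's azimuth by
        minimizing the smallest eigenvalue of K within
        ``orientation_window_deg`` of its nominal value.
    """
    B0 = np.asarray(B0, dtype=float)
    if len(B_list) != len(refs):
        raise ValueError("B_list and refs must have the same length")
    if len(refs) < 3:
        raise ValueError("at least three reference optics are required")
    if B0.shape != (4, 4):
        raise ValueError(f"B0 must be 4x4, got {B0.shape}")
    if np.linalg.cond(B0) > 1e12:
        raise CalibrationError("B0 is not invertible")

    B0_inv = np.linalg.inv(B0)
    cs = [B0_inv @ np.asarray(B) for B in B_list]
    refined = [_refine_from_eigenvalues(r, C) for r, C in zip(refs, cs)]

    def build_K(current: list[ReferenceOptic]) -> np.ndarray:
        return _normal_matrix([r.mueller() for r in current], cs)

    # nominal orientations that already explain the data to numerical
    # precision need no refinement (and refining on a flat objective
    # would only chase round-off noise)
    if refine_orientations:
        _, l0, l1, lmax = _smallest_two(build_K(refined))
        if l1 <= gap_threshold * lmax:
            # more than one near-null direction: no amount of orientation
            # refinement can make W unique
            refine_orientations = False
        elif l0 / max(l1, np.finfo(float).tiny) < 1e-12:
            refine_orientations = False

    if refine_orientations:
        for i, ref in enumerate(refined):
            lo = ref.orientation_deg - orientation_window_deg
            hi = ref.orientation_deg + orientation_window_deg

            def objective(theta: float, i=i) -> float:
                trial = list(refined)
                trial[i] = replace(trial[i], orientation_deg=theta % 180.0)
                _, l0, l1, _ = _smallest_two(build_K(trial))
                return l0 / max(l1, np.finfo(float).tiny)

            res = minimize_scalar(
                objective, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            refined[i] = replace(ref, orientation_deg=float(res.x) % 180.0)

    vec, l0, l1, lmax = _smallest_two(build_K(refined))
    if l1 <= gap_threshold * lmax:
        raise CalibrationError(
            "degenerate reference set: the second-smallest eigenvalue of K "
            f"({l1:.3g}) is not separated from zero (largest {lmax:.3g}); "
            "W is not uniquely determined"
        )
    residual = abs(l0) / l1
    if residual > gap_threshold:
        raise CalibrationError(
            "inconsistent calibration measurements: "
            f"eigenvalue ratio {residual:.3g} exceeds {gap_threshold:.3g}"
        )

    W = vec.reshape(4, 4, order="F")
    if W[0, 0] == 0:
        raise CalibrationError("recovered W has zero intensity in its first state")
    W = W / W[0, 0]
    A = B0 @ np.linalg.inv(W)
    return CalibrationResult(W=W, A=A, residual=residual, refined_refs=refined)


def calibrate_field(
    B0_stack,
    B_stacks,
    refs: list[ReferenceOptic],
    mode: str = "per_pixel",
    roi=None,
    **kwargs,
) -> CalibrationResult:
    """Calibrate every pixel independently, or once from ROI-averaged stacks.

    Per-pixel failures (degenerate or saturated pixels) are recorded in the
    result's ``mask`` instead of raising.  In ``global`` mode the stacks
    are averaged over ``roi`` (default: whole image) first.
    """
    b0 = B0_stack.b_matrices()
    bs = [s.b_matrices() for s in B_stacks]
    if any(b.shape != b0.shape for b in bs):
        raise ValueError("calibration stacks must share the same shape")

    if mode == "global":
        sl = (slice(None), slice(None)) if roi is None else roi.slices
        B0m = b0[sl].mean(axis=(0, 1))
        Bm = [b[sl].mean(axis=(0, 1)) for b in bs]
        return ecm_calibrate(B0m, Bm, refs, **kwargs)
    if mode != "per_pixel":
        raise ValueError(f"unknown mode {mode!r}")

    h, w = b0.shape[:2]
    W = np.full((h, w, 4, 4), np.nan)
    A = np.full((h, w, 4, 4), np.nan)
    residual = np.full((h, w), np.nan)
    mask = np.zeros((h, w), dtype=bool)
    refined = None
    for y in range(h):
        for x in range(w):
            try:
                res = ecm_calibrate(b0[y, x], [b[y, x] for b in bs], refs, **kwargs)
            except (CalibrationError, np.linalg.LinAlgError, ValueError):
                continue
            W[y, x] = res.W
            A[y, x] = res.A
            residual[y, x] = res.residual
            mask[y, x] = True
            refined = res.refined_refs
    if not mask.any():
        raise CalibrationError("calibration failed at every pixel")
    return CalibrationResult(
        W=W, A=A, residual=residual, refined_refs=refined or [], mask=mask
    )
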
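"""Canonical Mueller matrices and polarimeter state sets.

All matrices follow the Stokes convention (I, Q, U, V) with azimuths
measured in degrees from the horizontal.  Element (0, 0) of every
canonical builder is 1 (unit unpolarized transmittance); absolute
transmittance is applied as a scalar factor by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "isotropic_depolarizer",
    "linear_retarder",
    "linear_diattenuator",
    "linear_polarizer",
    "rotation_mueller",
    "tetrahedron_stokes",
    "default_psg_matrix",
    "default_psa_matrix",
]


def rotation_mueller(angle_deg: float) -> np.ndarray:
    """Mueller rotation matrix R(theta) acting on the (Q, U) plane.

    Rotating an element by theta maps its matrix M to R(theta) M R(-theta).
    """
    a = 2.0 * np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def isotropic_depolarizer(delta: float) -> np.ndarray:
    """Isotropic depolarizer diag(1, 1-delta, 1-delta, 1-delta).

    ``delta`` is the depolarization power in [0, 1]: 0 leaves polarization
    untouched, 1 fully depolarizes every input state.
    """
    k = 1.0 - float(delta)
    return np.diag([1.0, k, k, k])


def linear_retarder(retardance_deg: float, axis_deg: float = 0.0) -> np.ndarray:
    """Canonical linear retarder with phase ``retardance_deg`` at ``axis_deg``.

    A quarter-wave plate is ``retardance_deg=90``, a half-wave plate 180.
    """
    d = np.deg2rad(retardance_deg)
    cd, sd = np.cos(d), np.sin(d)
    m = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, -sd],
            [0.0, 0.0, sd, cd],
        ]
    )
    r = rotation_mueller(axis_deg)
    return r @ m @ r.T


def linear_diattenuator(diattenuation: float, axis_deg: float = 0.0) -> np.ndarray:
    """Canonical linear diattenuator, unit unpolarized transmittance.

    ``diattenuation`` D in [0, 1] is (T_max - T_min) / (T_max + T_min);
    D = 1 is an ideal polarizer.
    """
    dia = float(diattenuation)
    if not 0.0 <= dia <= 1.0:
        raise ValueError(f"diattenuation must be in [0, 1], got {dia}")
    q = np.sqrt(max(1.0 - dia * dia, 0.0))
    m = np.array(
        [
            [1.0, dia, 0.0, 0.0],
            [dia, 1.0, 0.0, 0.0],
            [0.0, 0.0, q, 0.0],
            [0.0, 0.0, 0.0, q],
        ]
    )
    r = rotation_mueller(axis_deg)
    return r @ m @ r.T


def linear_polarizer(axis_deg: float = 0.0, transmittance: float = 1.0) -> np.ndarray:
    """Ideal linear polarizer at ``axis_deg``.

    ``transmittance`` is the intensity transmittance for light polarized
    along the axis; the matrix equals (transmittance / 2) * (ideal
    projector), so its only nonzero eigenvalue is ``transmittance``.
    """
    c, s = np.cos(2 * np.deg2rad(axis_deg)), np.sin(2 * np.deg2rad(axis_deg))
    m = 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return float(transmittance) * m


def tetrahedron_stokes() -> np.ndarray:
    """Four fully polarized unit-intensity Stokes vectors, rows (4, 4).

    Their polarization parts form a regular tetrahedron on the Poincare
    sphere -- the classic minimum-condition-number choice for a four-state
    polarimeter.
    """
    s = 1.0 / np.sqrt(3.0)
    pts = np.array(
        [
            [1.0, s, s, s],
            [1.0, s, -s, -s],
            [1.0, -s, s, -s],
            [1.0, -s, -s, s],
        ]
    )
    return pts


def default_psg_matrix() -> np.ndarray:
    """Default modulation matrix W: columns are the PSG Stokes vectors."""
    return tetrahedron_stokes().T.copy()


def default_psa_matrix() -> np.ndarray:
    """Default analysis matrix A: rows are the PSA Stokes vectors.

    Detected intensities are row . M . column up to the detector gain,
    which is absorbed into the photon budget.
    """
    return tetrahedron_stokes()
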
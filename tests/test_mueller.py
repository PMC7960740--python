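import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muellerpol import (
    AcquisitionConfig,
    CalibrationResult,
    IntensityStack,
    decompose_map,
    linear_retardance,
    lu_chipman,
    lu_chipman_batch,
    make_scene,
    physical_realizability,
    reconstruct,
    retarder_axis,
    scene_to_mueller,
    simulate_acquisition,
)
from muellerpol.mueller import MuellerMap, coherency_matrix
from muellerpol.optics import (
    isotropic_depolarizer,
    linear_diattenuator,
    linear_retarder,
)

from conftest import random_physical_mueller


# ---------------------------------------------------------------------------
# lu_chipman on canonical matrices


@pytest.mark.parametrize(
    "matrix, exp_delta, exp_ret, exp_diatt",
    [
        (np.eye(4), 0.0, 0.0, 0.0),
        (np.diag([1.0, 0.5, 0.5, 0.5]), 0.5, 0.0, 0.0),
        (np.diag([1.0, 0.0, 0.0, 0.0]), 1.0, 0.0, 0.0),
        (linear_retarder(180.0, 0.0), 0.0, 180.0, 0.0),
        (linear_retarder(90.0, 30.0), 0.0, 90.0, 0.0),
        (linear_diattenuator(0.3, 0.0), 0.0, 0.0, 0.3),
    ],
)
def test_lu_chipman_canonical(matrix, exp_delta, exp_ret, exp_diatt):
    _, _, _, diatt, delta, ret = lu_chipman(matrix)
    assert delta == pytest.approx(exp_delta, abs=1e-12)
    assert ret == pytest.approx(exp_ret, abs=1e-6)
    assert diatt == pytest.approx(exp_diatt, abs=1e-12)


def test_lu_chipman_requires_normalization():
    with pytest.raises(ValueError, match="normalized"):
        lu_chipman(2 * np.eye(4))


def test_compose_then_decompose_recovers_parameters():
    M = (
        isotropic_depolarizer(0.3)
        @ linear_retarder(72.0, 25.0)
        @ linear_diattenuator(0.1, 0.0)
    )
    M_D, M_delta, M_R, diatt, delta, ret = lu_chipman(M)
    assert delta == pytest.approx(0.3, abs=1e-8)
    assert ret == pytest.approx(72.0, abs=1e-8)
    assert diatt == pytest.approx(0.1, abs=1e-8)
    assert float(retarder_axis(M_R)) == pytest.approx(25.0, abs=1e-8)
    np.testing.assert_allclose(M_delta @ M_R @ M_D, M, atol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    delta=st.floats(0.0, 0.95),
    ret=st.floats(0.0, 179.0),
    axis=st.floats(0.0, 179.9),
    diatt=st.floats(0.0, 0.9),
)
def test_factor_consistency_property(delta, ret, axis, diatt):
    """M_delta . M_R . M_D reproduces the input; ranges honored; M_R orthogonal."""
    M = (
        isotropic_depolarizer(delta)
        @ linear_retarder(ret, axis)
        @ linear_diattenuator(diatt, 0.0)
    )
    M_D, M_delta, M_R, d_rec, delta_rec, ret_rec = lu_chipman(M)
    np.testing.assert_allclose(M_delta @ M_R @ M_D, M, atol=1e-10)
    assert 0.0 <= delta_rec <= 1.0
    assert 0.0 <= ret_rec <= 180.0
    assert 0.0 <= d_rec <= 1.0
    r3 = M_R[1:, 1:]
    np.testing.assert_allclose(r3.T @ r3, np.eye(3), atol=1e-8)


@pytest.mark.parametrize("k", [1.0, 0.75, 0.5, 0.2, 0.0])
def test_isotropic_depolarizer_delta_is_one_minus_k(k):
    _, _, _, _, delta, _ = lu_chipman(np.diag([1.0, k, k, k]))
    assert delta == pytest.approx(1.0 - k, abs=1e-14)


def test_near_ideal_polarizer_is_clamped_not_crashed():
    M = linear_diattenuator(1.0, 20.0)
    res = lu_chipman_batch(M[None])
    assert res.d_clamp_count == 1
    assert np.isfinite(res.delta).all()


def test_linear_retardance_matches_total_for_pure_linear_retarder():
    M_R = linear_retarder(58.0, 40.0)
    assert float(linear_retardance(M_R)) == pytest.approx(58.0, abs=1e-10)


# ---------------------------------------------------------------------------
# reconstruction


def test_reconstruct_identity_instrument_returns_matrix_itself():
    M = random_physical_mueller(np.random.default_rng(0), 1)[0]
    b = np.broadcast_to(M, (2, 3, 4, 4))
    stack = IntensityStack.from_b_matrices(b)
    cal = CalibrationResult(W=np.eye(4), A=np.eye(4), residual=0.0)
    mm = reconstruct(stack, cal)
    np.testing.assert_allclose(mm.matrices[0, 0] * mm.m11[0, 0], M, atol=1e-12)


def test_reconstruct_round_trip_random_instrument():
    rng = np.random.default_rng(7)
    M = random_physical_mueller(rng, 6).reshape(2, 3, 4, 4)
    A = rng.uniform(0.5, 1.5, (4, 4)) + np.eye(4)
    W = rng.uniform(0.5, 1.5, (4, 4)) + np.eye(4)
    b = A @ M @ W
    stack = IntensityStack.from_b_matrices(b)
    mm = reconstruct(stack, CalibrationResult(W=W, A=A, residual=0.0))
    rec = mm.matrices * mm.m11[..., None, None]
    assert np.abs(rec - M).max() < 1e-10


def test_reconstruct_scaling_moves_only_m11(noiseless_acq, true_calibration):
    scene = make_scene(8, 8, seed=1)
    stack = simulate_acquisition(scene_to_mueller(scene), noiseless_acq)
    scaled = IntensityStack(frames=stack.frames * 7.0)
    mm = reconstruct(stack, true_calibration)
    mm7 = reconstruct(scaled, true_calibration)
    np.testing.assert_allclose(mm7.m11, 7.0 * mm.m11, rtol=1e-12)
    np.testing.assert_allclose(mm7.matrices, mm.matrices, atol=1e-12)


def test_reconstruct_masks_singular_calibration():
    b = np.broadcast_to(np.eye(4), (2, 2, 4, 4))
    stack = IntensityStack.from_b_matrices(b)
    A = np.broadcast_to(np.eye(4), (2, 2, 4, 4)).copy()
    A[0, 0] = 0.0  # singular at one pixel
    cal = CalibrationResult(W=np.eye(4), A=A, residual=0.0)
    mm = reconstruct(stack, cal)
    assert not mm.mask[0, 0]
    assert mm.mask[1, 1]


# ---------------------------------------------------------------------------
# map-level decomposition


def test_decompose_map_recovers_scene(noiseless_acq, true_calibration):
    scene = make_scene(16, 12, seed=5)
    stack = simulate_acquisition(scene_to_mueller(scene), noiseless_acq)
    dec = decompose_map(reconstruct(stack, true_calibration))
    assert np.abs(dec.delta - scene.delta_map).max() < 1e-8
    assert np.abs(dec.retardance - scene.retardance_map).max() < 1e-8


def test_decompose_map_propagates_mask():
    mats = np.broadcast_to(np.eye(4), (4, 4, 4, 4)).copy()
    mask = np.ones((4, 4), dtype=bool)
    mask[1, 2] = False
    dec = decompose_map(MuellerMap(matrices=mats, m11=np.ones((4, 4)), mask=mask))
    assert np.isnan(dec.delta[1, 2])
    assert np.isfinite(dec.delta[mask]).all()
    np.testing.assert_allclose(dec.delta[mask], 0.0, atol=1e-14)


def test_decompose_is_pixel_order_independent(noiseless_acq, true_calibration):
    scene = make_scene(8, 10, seed=9)
    stack = simulate_acquisition(scene_to_mueller(scene), noiseless_acq)
    mm = reconstruct(stack, true_calibration)
    dec = decompose_map(mm)
    # permuting the pixels permutes the outputs identically
    flat = mm.matrices.reshape(-1, 4, 4)
    perm = np.random.default_rng(0).permutation(flat.shape[0])
    res = lu_chipman_batch(flat[perm])
    np.testing.assert_array_equal(res.delta, dec.delta.reshape(-1)[perm])


def test_retardance_noise_shrinks_with_photon_budget(true_calibration):
    """Per-pixel retardance: small bias, SD scaling ~ 1/sqrt(budget)."""
    scene = make_scene(
        24, 24, delta=0.2, retardance=40.0, retarder_axis=10.0, diattenuation=0.0,
        m11=1.0, seed=0,
    )
    mm = scene_to_mueller(scene)
    sds = []
    for budget in (10_000.0, 40_000.0):
        stack = simulate_acquisition(
            mm,
            AcquisitionConfig(noise_model="poisson", photon_budget=budget, seed=3),
        )
        dec = decompose_map(reconstruct(stack, true_calibration))
        err = dec.retardance - 40.0
        assert abs(err.mean()) < err.std()  # bias below the noise floor
        sds.append(err.std())
    assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.2)


# ---------------------------------------------------------------------------
# physical realizability


def test_coherency_trace_equals_m00():
    M = random_physical_mueller(np.random.default_rng(3), 1)[0]
    T = coherency_matrix(M)
    assert np.isclose(np.real(np.trace(T)), M[0, 0])


@pytest.mark.parametrize(
    "matrix, expected",
    [
        (np.eye(4), True),
        (np.diag([1.0, 1.0, -1.0, -1.0]), True),  # half-wave plate
        (np.diag([1.0, 1.5, 0.0, 0.0]), False),  # overpolarizing
        # maps Stokes to Stokes but is no mixture of deterministic elements
        (np.diag([1.0, 1.0, 1.0, -1.0]), False),
    ],
)
def test_physical_realizability_cases(matrix, expected):
    ok, min_eig = physical_realizability(matrix)
    assert ok is expected


def test_identity_coherency_spectrum():
    eigs = np.linalg.eigvalsh(coherency_matrix(np.eye(4)))
    np.testing.assert_allclose(eigs, [0.0, 0.0, 0.0, 1.0], atol=1e-12)
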
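import numpy as np
import pytest

from muellerpol import (
    AcquisitionConfig,
    ContractionScene,
    PshgScene,
    make_scene,
    scene_to_mueller,
    simulate_acquisition,
    simulate_calibration_set,
    simulate_contraction_pair,
    simulate_pshg_stack,
)
from muellerpol.optics import linear_retarder


# ---------------------------------------------------------------------------
# make_scene


def test_constant_field_mode_is_exact():
    scene = make_scene(8, 8, delta=0.3, retardance=40.0, retarder_axis=10.0,
                       diattenuation=0.0, m11=1.0, seed=0)
    np.testing.assert_array_equal(scene.delta_map, 0.3)
    np.testing.assert_array_equal(scene.retardance_map, 40.0)
    np.testing.assert_array_equal(scene.retarder_axis_map, 10.0)


def test_same_seed_same_scene():
    a = make_scene(16, 16, seed=42)
    b = make_scene(16, 16, seed=42)
    np.testing.assert_array_equal(a.delta_map, b.delta_map)
    np.testing.assert_array_equal(a.retardance_map, b.retardance_map)
    c = make_scene(16, 16, seed=43)
    assert not np.array_equal(a.delta_map, c.delta_map)


def test_scene_respects_ranges():
    scene = make_scene(32, 32, delta=(0.1, 0.6), retardance=(5, 60), seed=3)
    assert scene.delta_map.min() >= 0.1 and scene.delta_map.max() <= 0.6
    assert scene.retardance_map.min() >= 5 and scene.retardance_map.max() <= 60


def test_length_scale_controls_smoothness():
    def roughness(length_scale):
        scene = make_scene(64, 64, delta=(0.2, 0.4), length_scale=length_scale, seed=0)
        f = scene.delta_map
        return np.abs(np.diff(f, axis=0)).mean() / f.std()

    assert roughness(10.0) < roughness(2.0) < roughness(0.5)
    scene = make_scene(64, 64, delta=(0.2, 0.4), length_scale=10.0, seed=0)
    assert scene.delta_map.mean() == pytest.approx(0.3, abs=0.02)


def test_scene_validation():
    with pytest.raises(ValueError, match="8x8"):
        make_scene(4, 4)
    with pytest.raises(ValueError, match="delta"):
        make_scene(8, 8, delta=1.2)


# ---------------------------------------------------------------------------
# scene_to_mueller


def test_trivial_scene_gives_identity():
    scene = make_scene(8, 8, delta=0.0, retardance=0.0, retarder_axis=0.0,
                       diattenuation=0.0, m11=1.0, seed=0)
    mm = scene_to_mueller(scene)
    np.testing.assert_allclose(
        mm.matrices, np.broadcast_to(np.eye(4), mm.matrices.shape), atol=1e-14
    )


def test_pure_depolarizer_scene():
    scene = make_scene(8, 8, delta=0.5, retardance=0.0, retarder_axis=0.0,
                       diattenuation=0.0, m11=1.0, seed=0)
    mm = scene_to_mueller(scene)
    np.testing.assert_allclose(
        mm.matrices,
        np.broadcast_to(np.diag([1, 0.5, 0.5, 0.5]), mm.matrices.shape),
        atol=1e-14,
    )


def test_pure_retarder_scene_matches_canonical_matrix():
    scene = make_scene(8, 8, delta=0.0, retardance=90.0, retarder_axis=0.0,
                       diattenuation=0.0, m11=1.0, seed=0)
    mm = scene_to_mueller(scene)
    np.testing.assert_allclose(mm.matrices[3, 3], linear_retarder(90.0, 0.0), atol=1e-14)


def test_mueller_entries_bounded_by_m11():
    scene = make_scene(16, 16, diattenuation=(0.0, 0.5), seed=8)
    mm = scene_to_mueller(scene)
    assert np.abs(mm.matrices).max() <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# simulate_acquisition


def test_identity_instrument_identity_sample_yields_identity_frames():
    from muellerpol.mueller import MuellerMap

    mm = MuellerMap(
        matrices=np.broadcast_to(np.eye(4), (2, 2, 4, 4)).copy(),
        m11=np.ones((2, 2)),
    )
    cfg = AcquisitionConfig(
        W_true=np.eye(4), A_true=np.eye(4), photon_budget=1.0, noise_model="none"
    )
    stack = simulate_acquisition(mm, cfg)
    np.testing.assert_array_equal(stack.b_matrices()[0, 0], np.eye(4))


def test_poisson_acquisition_is_seed_deterministic():
    scene = make_scene(8, 8, seed=2)
    mm = scene_to_mueller(scene)
    cfg = AcquisitionConfig(noise_model="poisson", seed=5)
    a = simulate_acquisition(mm, cfg)
    b = simulate_acquisition(mm, cfg)
    np.testing.assert_array_equal(a.frames, b.frames)
    c = simulate_acquisition(mm, AcquisitionConfig(noise_model="poisson", seed=6))
    assert not np.array_equal(a.frames, c.frames)


def test_negative_intensity_raises_with_location():
    from muellerpol.mueller import MuellerMap

    mm = MuellerMap(
        matrices=np.broadcast_to(np.diag([1.0, 1.0, -1.0, -1.0]), (2, 2, 4, 4)).copy(),
        m11=np.ones((2, 2)),
    )
    cfg = AcquisitionConfig(
        W_true=np.eye(4), A_true=np.eye(4), photon_budget=1.0, noise_model="none"
    )
    with pytest.raises(ValueError, match=r"pixel \(y=0, x=0\)"):
        simulate_acquisition(mm, cfg)


def test_config_validation():
    with pytest.raises(ValueError, match="photon_budget"):
        AcquisitionConfig(photon_budget=0.0)
    with pytest.raises(ValueError, match="invertible"):
        AcquisitionConfig(W_true=np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# calibration set


def test_empty_reference_list_yields_only_b0():
    cfg = AcquisitionConfig(noise_model="none")
    cal_set = simulate_calibration_set(cfg, [], shape=(2, 2))
    assert cal_set.B_list == []
    assert cal_set.M_true == []


def test_identity_instrument_b0_is_identity_pattern():
    cfg = AcquisitionConfig(
        W_true=np.eye(4), A_true=np.eye(4), photon_budget=1.0, noise_model="none"
    )
    cal_set = simulate_calibration_set(cfg, [], shape=(2, 2))
    np.testing.assert_array_equal(cal_set.B0.b_matrices()[1, 0], np.eye(4))


# ---------------------------------------------------------------------------
# contraction pair


def test_contraction_ground_truth_geometry():
    scene = ContractionScene(
        shape=(100, 100),
        day0_rect=(10, 10, 90, 90),
        day3_ellipse=(50, 50, 20, 16),
        seed=0,
    )
    _, _, truth = simulate_contraction_pair(scene)
    assert truth["area_ratio"] == pytest.approx(np.pi * 20 * 16 / 6400)
    half = ContractionScene(
        shape=(100, 100),
        day0_rect=(10, 10, 90, 90),
        day3_ellipse=(50, 50, 10, 8),
        seed=0,
    )
    _, _, t2 = simulate_contraction_pair(half)
    assert t2["area_ratio"] == pytest.approx(truth["area_ratio"] / 4)


def test_contraction_equal_intensities_give_unit_ratio():
    scene = ContractionScene(
        shape=(64, 64),
        day0_rect=(4, 4, 60, 60),
        day3_ellipse=(32, 32, 10, 10),
        sample_intensity=150.0,
        background_intensity=150.0,
        seed=0,
    )
    _, _, truth = simulate_contraction_pair(scene)
    assert truth["intensity_ratio"] == 1.0


def test_contraction_scene_validation():
    with pytest.raises(ValueError, match="inside"):
        ContractionScene(
            shape=(64, 64), day0_rect=(4, 4, 40, 40), day3_ellipse=(32, 32, 20, 20)
        )


# ---------------------------------------------------------------------------
# pSHG stacks


def test_zero_anisotropy_gives_identical_frames():
    scene = PshgScene(orientation_field=np.full((4, 4), 30.0), anisotropy=0.0)
    stack, _ = simulate_pshg_stack(scene)
    assert stack.frames.shape[0] == 18
    np.testing.assert_allclose(
        stack.frames, np.broadcast_to(stack.frames[0], stack.frames.shape), atol=1e-12
    )


def test_pshg_seed_determinism():
    scene = PshgScene(
        orientation_field=np.full((4, 4), 30.0), noise_model="poisson", seed=4
    )
    a, _ = simulate_pshg_stack(scene)
    b, _ = simulate_pshg_stack(scene)
    np.testing.assert_array_equal(a.frames, b.frames)


def test_pshg_anisotropy_above_one_rejected():
    with pytest.raises(ValueError, match="anisotropy"):
        PshgScene(orientation_field=np.zeros((4, 4)), anisotropy=1.5)
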
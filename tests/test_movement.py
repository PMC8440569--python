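"""Canonicalization, mirroring and movement-model library construction."""

import math

import numpy as np
import pytest

from domreg import (
    ModelConfig,
    SimConfig,
    build_library,
    canonicalize,
    compute_kinematics,
    generate_match,
    load_library,
    mirror,
    rotation_angle,
    save_library,
    smooth_trajectory,
    Trajectory,
)
from tests.conftest import make_uniform_dataset


class TestRotationAngle:
    @pytest.mark.parametrize(
        "theta_d, expected",
        [(90.0, 0.0), (0.0, 90.0), (-45.0, 135.0), (180.0, -90.0), (-90.0, 180.0)],
    )
    def test_branches(self, theta_d, expected):
        assert rotation_angle(theta_d) == pytest.approx(expected)


def _straight_traj(speed, heading_deg, n=200, fr=30.0, start=(30.0, 30.0)):
    t = np.arange(n) / fr
    h = math.radians(heading_deg)
    return Trajectory(
        player_id="p",
        t=t,
        x=start[0] + speed * math.cos(h) * t,
        y=start[1] + speed * math.sin(h) * t,
    )


class TestCanonicalize:
    def test_moving_along_y_is_identity(self):
        traj = _straight_traj(2.0, 90.0)
        kin = compute_kinematics(traj)
        seg = canonicalize(traj, kin, frame=10, horizon_s=1.0)
        assert seg.theta_r == pytest.approx(0.0)
        # canonical positions equal raw relative positions
        np.testing.assert_allclose(seg.fp[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            seg.fp[:, 1], 2.0 * (np.arange(1, 31) / 30.0), rtol=1e-9
        )

    def test_moving_along_x_rotates_onto_y(self):
        traj = _straight_traj(3.0, 0.0)
        kin = compute_kinematics(traj)
        seg = canonicalize(traj, kin, frame=10, horizon_s=1.0)
        assert seg.theta_r == pytest.approx(90.0)
        np.testing.assert_allclose(seg.fp[-1], [0.0, 3.0], atol=1e-9)

    def test_diagonal_example(self):
        # movement at -45 deg; a future point at relative (1, -1) lies on the
        # movement direction and must map to (0, sqrt(2))
        traj = _straight_traj(3.0, -45.0)
        kin = compute_kinematics(traj)
        frame = 10
        seg = canonicalize(traj, kin, frame, horizon_s=1.0)
        assert seg.theta_r == pytest.approx(135.0)
        step = np.hypot(*(seg.fp[0]))
        rel = np.array([1.0, -1.0])
        rad = math.radians(135.0)
        expected = np.array(
            [
                math.cos(rad) * rel[0] - math.sin(rad) * rel[1],
                math.sin(rad) * rel[0] + math.cos(rad) * rel[1],
            ]
        )
        np.testing.assert_allclose(expected, [0.0, math.sqrt(2)], atol=1e-12)
        # all canonical points lie on the +y axis for straight-line motion
        np.testing.assert_allclose(seg.fp[:, 0], 0.0, atol=1e-9)
        assert np.all(seg.fp[:, 1] > 0)
        assert step > 0

    def test_masked_frame_and_short_future_are_errors(self):
        traj = _straight_traj(2.0, 0.0, n=100)
        kin = compute_kinematics(traj)
        with pytest.raises(ValueError, match="masked"):
            canonicalize(traj, kin, frame=0, horizon_s=1.0)
        with pytest.raises(ValueError, match="future"):
            canonicalize(traj, kin, frame=95, horizon_s=1.0)


class TestMirror:
    def test_single_sample_doubles(self):
        out = mirror(np.array([[[0.5, 2.0]]]))
        assert out.shape == (2, 1, 2)
        np.testing.assert_array_equal(
            sorted(out[:, 0, 0].tolist()), [-0.5, 0.5]
        )
        np.testing.assert_array_equal(out[:, 0, 1], [2.0, 2.0])

    def test_axis_sample_kept_twice(self):
        out = mirror(np.array([[[0.0, 2.0]]]))
        assert out.shape == (2, 1, 2)
        np.testing.assert_array_equal(out[0], out[1])

    def test_full_segment_symmetric_at_every_lag(self):
        rng = np.random.default_rng(3)
        seg = rng.normal(size=(7, 90, 2))
        out = mirror(seg)
        assert out.shape == (14, 90, 2)
        for lag in range(90):
            xs = out[:, lag, 0]
            np.testing.assert_array_equal(np.sort(xs), np.sort(-xs))
            np.testing.assert_array_equal(out[:7, lag, 1], out[7:, lag, 1])


class TestBinning:
    def test_sprint_state_bin_assignment(self):
        cfg = ModelConfig()
        vi, ai = cfg.bin_of(5.4, 2.2)
        assert (cfg.speed_edges[vi], cfg.speed_edges[vi + 1]) == (5.0, 6.0)
        assert (cfg.accel_edges[ai], cfg.accel_edges[ai + 1]) == (2.0, 3.0)

    def test_out_of_range_clamps_to_edge_bins(self):
        cfg = ModelConfig()
        vi, ai = cfg.bin_of(12.0, -10.0)
        assert cfg.speed_edges[vi] == 9.0
        assert cfg.accel_edges[ai + 1] == -5.0
        vi, ai = cfg.bin_of(10.0, 6.0)
        assert cfg.speed_edges[vi] == 9.0      # right edge folds into [9, 10)
        assert cfg.accel_edges[ai] == 5.0


class TestBuildLibrary:
    def test_uniform_agent_populates_expected_cells(self):
        # constant 5.5 m/s: populated cells sit in the v in [5,6) column;
        # zero acceleration lies exactly on the a = 0 bin edge, so numerical
        # noise may split mass between a in [-1,0) and [0,1)
        ds = make_uniform_dataset([(5.5, 0.0)], [(5.0, 30.0)], duration_s=15.0)
        lib = build_library(ds, ds.config, ModelConfig(min_samples=50))
        occupied = set(map(tuple, np.argwhere(lib.occupancy)))
        assert occupied <= {(5, 5), (5, 6)} and occupied
        for vi, ai in occupied:
            pts = lib.models[(vi, ai)].points_at(30)  # lag 30 = 1 s
            np.testing.assert_allclose(pts[:, 0].mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(pts[:, 1], 5.5, atol=0.3)

    def test_two_frame_dataset_yields_empty_library(self):
        # 4 s = 120 frames: no frame has a full 4 s future window
        ds = make_uniform_dataset([(3.0, 0.0)], [(5.0, 30.0)], duration_s=4.0)
        lib = build_library(
            ds, ds.config, ModelConfig(horizon_s=4.0, min_samples=1)
        )
        assert lib.models == {}
        assert not lib.occupancy.any()

    def test_mirror_mean_is_exactly_zero(self, crw_library):
        for model in crw_library.models.values():
            xs = model.samples[:, :, 0]
            n = xs.shape[0] // 2
            # pairing originals with mirrored copies cancels exactly
            np.testing.assert_array_equal(xs[:n], -xs[n:])

    def test_kinematic_reach_envelope(self):
        # straight-line agents have no filtering artifacts: max radial
        # offset at lag i must respect v_u * t + 0.5 * a_max * t^2
        ds = make_uniform_dataset(
            [(2.5, 0.0), (5.0, 45.0)], [(10.0, 10.0), (10.0, 20.0)],
            duration_s=15.0,
        )
        lib = build_library(ds, ds.config, ModelConfig(min_samples=10))
        for model in lib.models.values():
            vu = model.v_range[1]
            H = model.horizon_frames
            for lag in (1, 30, 60, 90):
                if lag > H:
                    continue
                t = lag / 30.0
                r = np.hypot(*model.points_at(lag).T).max()
                assert r <= vu * t + 0.5 * 6.0 * t**2 + 1e-6

    def test_deterministic_and_serialization_round_trip(self, tmp_path, crw_match):
        dataset, _ = crw_match
        cfg = ModelConfig(min_samples=100)
        lib1 = build_library(dataset, dataset.config, cfg)
        lib2 = build_library(dataset, dataset.config, cfg)
        assert set(lib1.models) == set(lib2.models)
        for key in lib1.models:
            np.testing.assert_array_equal(
                lib1.models[key].samples, lib2.models[key].samples
            )
        path = tmp_path / "lib.npz"
        save_library(lib1, path)
        lib3 = load_library(path)
        assert set(lib3.models) == set(lib1.models)
        for key in lib1.models:
            np.testing.assert_array_equal(
                lib1.models[key].samples, lib3.models[key].samples
            )
        assert lib3.model_config == lib1.model_config
        assert lib3.pitch_config == lib1.pitch_config

    def test_manifest_mismatch_detected(self, tmp_path, uniform_library):
        import json

        lib, _ = uniform_library
        path = tmp_path / "lib.npz"
        save_library(lib, path)
        with np.load(path) as data:
            payload = {k: data[k] for k in data.files}
        manifest = json.loads(str(payload["manifest"]))
        manifest["config_hash"] = "0" * 64
        payload["manifest"] = json.dumps(manifest)
        np.savez_compressed(tmp_path / "bad.npz", **payload)
        with pytest.raises(ValueError, match="hash"):
            load_library(tmp_path / "bad.npz")


class TestFallback:
    def test_lookup_in_populated_cell(self, uniform_library):
        lib, _ = uniform_library
        before = lib.fallback_count
        model = lib.lookup(3.0, 0.5)
        assert model.v_range == (3.0, 4.0)
        assert lib.fallback_count == before

    def test_fallback_to_nearest_populated(self, uniform_library):
        lib, _ = uniform_library
        before = lib.fallback_count
        model = lib.lookup(9.5, 5.5)  # sprint bin never trained
        assert (model.v_index, model.a_index) in lib.models
        assert lib.occupancy[model.v_index, model.a_index]
        assert lib.fallback_count == before + 1
        # deterministic: same query, same cell
        again = lib.lookup(9.5, 5.5)
        assert (again.v_index, again.a_index) == (model.v_index, model.a_index)

    def test_empty_library_raises(self, default_pitch):
        from domreg.movement import ModelLibrary

        lib = ModelLibrary(pitch_config=default_pitch, model_config=ModelConfig())
        with pytest.raises(ValueError, match="no populated"):
            lib.lookup(1.0, 0.0)
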
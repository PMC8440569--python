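"""Accuracy protocol, pass-window percentiles and the area comparison."""

import itertools
import math

import numpy as np
import pytest

from domreg import (
    ModelConfig,
    PassEvent,
    TrackingDataset,
    build_library,
    compare_areas,
    pass_windows,
)
from domreg.evaluation import accuracy, area_protocol, evaluate_match
from tests.conftest import make_uniform_dataset


def _slow_far_apart(duration=20.0):
    return make_uniform_dataset(
        [(0.5, 0.0), (0.5, 90.0), (0.5, 180.0), (0.5, -90.0)],
        [(20.0, 20.0), (80.0, 20.0), (80.0, 50.0), (20.0, 50.0)],
        duration_s=duration,
    )


class TestAccuracy:
    def test_slow_far_apart_agents_self_predict(self):
        # slow movers far apart: every future position stays inside the
        # player's own reach cloud, so accuracy is 100% at all horizons
        ds = _slow_far_apart()
        lib = build_library(ds, ds.config, ModelConfig(min_samples=20))
        with pytest.warns(UserWarning, match="overlap"):
            report = accuracy(ds, lib, stride=30)
        for pid, by_T in report.per_player.items():
            for T, pct in by_T.items():
                assert pct == 100.0, (pid, T)

    def test_matches_brute_force_recount(self, uniform_library):
        # recount hits with the public full-grid pipeline on the same frames
        from domreg import PlayerState, compute_dominance, player_probability
        from domreg.evaluation import _PlayerSeries

        lib, ds = uniform_library
        cfg = lib.model_config
        stride = 90
        report = accuracy(ds, lib, horizons=(1.0,), stride=stride)
        series = {pid: _PlayerSeries(ds, pid, cfg) for pid in ds.players}
        hits = {pid: 0 for pid in ds.players}
        counts = {pid: 0 for pid in ds.players}
        for frame in ds.frames[::stride]:
            grids = []
            for pid, s in series.items():
                idx = s.index_of(frame)
                if idx is None or not s.kin.valid[idx]:
                    continue
                state = PlayerState(
                    position=(s.traj.x[idx], s.traj.y[idx]),
                    theta_d=float(s.kin.theta_d[idx]),
                    v=float(s.kin.v[idx]), a=float(s.kin.a[idx]), frame=int(frame),
                )
                grids.append(
                    player_probability(lib, state, horizon_s=1.0, player_id=pid)
                )
            if not grids:
                continue
            dmap = compute_dominance(grids)
            for pid in [g.player_id for g in grids]:
                s = series[pid]
                fut = s.index_of(frame + 30)
                if fut is None:
                    continue
                row, col = lib.pitch_config.cell_of(s.raw_x[fut], s.raw_y[fut])
                if not lib.pitch_config.on_pitch_cells(row, col):
                    continue
                counts[pid] += 1
                if dmap.owner_at(s.raw_x[fut], s.raw_y[fut]) == pid:
                    hits[pid] += 1
        for pid in ds.players:
            if counts[pid] == 0:
                continue
            expected = 100.0 * hits[pid] / counts[pid]
            assert report.per_player[pid][1.0] == pytest.approx(expected)
            assert report.evaluated[pid][1.0] == counts[pid]

    def test_translation_invariance_by_whole_cells(self, uniform_library):
        lib, ds = uniform_library
        moved = ds.data.copy()
        moved["x_m"] += 0.5   # exactly 5 cells: raster alignment preserved
        moved["y_m"] += 0.5
        ds2 = TrackingDataset(data=moved, config=ds.config)
        r1 = accuracy(ds, lib, horizons=(1.0,), stride=60)
        r2 = accuracy(ds2, lib, horizons=(1.0,), stride=60)
        for pid in r1.per_player:
            assert r1.per_player[pid][1.0] == pytest.approx(
                r2.per_player[pid][1.0]
            )

    def test_relabeling_invariance(self, uniform_library):
        lib, ds = uniform_library
        renamed = ds.data.copy()
        renamed["player_id"] = "Z" + renamed["player_id"].astype(str)
        ds2 = TrackingDataset(data=renamed, config=ds.config)
        r1 = accuracy(ds, lib, horizons=(1.0,), stride=60)
        r2 = accuracy(ds2, lib, horizons=(1.0,), stride=60)
        for pid in r1.per_player:
            assert r1.per_player[pid][1.0] == pytest.approx(
                r2.per_player["Z" + pid][1.0]
            )

    def test_horizon_beyond_library_rejected(self, uniform_library):
        lib, ds = uniform_library
        with pytest.raises(ValueError, match="horizon"):
            accuracy(ds, lib, horizons=(5.0,))


class TestPassWindows:
    def test_constant_windows(self):
        events = [PassEvent(i * 100, i * 100 + 30, "a", "b") for i in range(20)]
        rep = pass_windows(events, frame_rate=30.0)
        assert rep.n == 20
        assert rep.p25 == rep.p50 == rep.p75 == rep.p95 == pytest.approx(1.0)
        assert rep.recommended_horizon_s == pytest.approx(1.0)

    def test_linear_interpolation_median(self):
        # windows 0.1..2.0 s in 0.1 steps: the interpolated median is 1.05
        events = [
            PassEvent(i * 100, i * 100 + 3 * (i + 1), "a", "b") for i in range(20)
        ]
        rep = pass_windows(events, frame_rate=30.0)
        assert rep.p50 == pytest.approx(1.05)

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(10, 120, size=50)
        events = [PassEvent(i * 200, i * 200 + int(w), "a", "b")
                  for i, w in enumerate(lengths)]
        shuffled = [events[i] for i in rng.permutation(50)]
        r1, r2 = pass_windows(events), pass_windows(shuffled)
        assert (r1.p25, r1.p50, r1.p75, r1.p95) == (r2.p25, r2.p50, r2.p75, r2.p95)

    def test_failed_passes_excluded(self):
        events = [
            PassEvent(0, 30, "a", "b", success=True),
            PassEvent(100, 160, "a", "b", success=False),
        ]
        assert pass_windows(events).n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="successful"):
            pass_windows([])

    def test_reception_before_pass_unconstructible(self):
        with pytest.raises(ValueError, match="reception_frame"):
            PassEvent(100, 90, "a", "b")


class TestCompareAreas:
    def test_identical_samples_null(self):
        x = np.arange(30.0)
        res = compare_areas(x, x.copy(), seed=0)
        assert res.p_value > 0.9
        assert res.r < 0.05
        assert res.label == "negligible"

    def test_exact_enumeration_oracle(self):
        # all 184756 equally-likely assignments of ranks 1..20 to sample 1:
        # the observed rank sum 55 is the unique minimum, so the two-sided
        # exact p-value is 2 / C(20, 10)
        x = np.arange(1.0, 11.0)
        y = np.arange(11.0, 21.0)
        obs = x.sum()
        count_le = sum(
            1 for comb in itertools.combinations(range(1, 21), 10)
            if sum(comb) <= obs
        )
        total = math.comb(20, 10)
        p_exact = 2.0 * count_le / total
        res = compare_areas(x, y, seed=0)
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)
        assert res.label == "large"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(3.0, 30.0, size=100)
        y = rng.gamma(3.0, 55.0, size=120)
        r1 = compare_areas(x, y, seed=1)
        r2 = compare_areas(y, x, seed=1)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.r == pytest.approx(r2.r, rel=1e-9)

    def test_bootstrap_ci_brackets_median(self):
        rng = np.random.default_rng(2)
        x = rng.normal(73.0, 10.0, size=200)
        y = rng.normal(171.0, 60.0, size=200)
        res = compare_areas(x, y, seed=3)
        assert res.model_ci95[0] <= res.model_median <= res.model_ci95[1]
        assert res.voronoi_ci95[0] <= res.voronoi_median <= res.voronoi_ci95[1]
        assert res.model_iqr >= 0 and res.voronoi_iqr >= 0
        assert 0 <= res.r <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_areas(np.array([]), np.array([1.0]))


class TestEndToEnd:
    def test_evaluate_match_report_structure(self, crw_match, crw_library):
        dataset, events = crw_match
        with pytest.warns(UserWarning, match="overlap"):
            report = evaluate_match(
                dataset, crw_library, events=events, stride=150, seed=0
            )
        acc = report["accuracy"]["summary"]
        assert set(acc) == {"1.0", "2.0", "3.0"}
        for block in acc.values():
            assert 0.0 <= block["mean"] <= 100.0
        areas = report["areas"]
        assert areas["model"]["median_m2"] > 0
        assert areas["voronoi"]["median_m2"] > 0
        assert 0 < areas["free_space"]["median_fraction_of_pitch"] < 1
        assert 0 <= areas["rank_sum"]["p_value"] <= 1
        if events:
            assert report["pass_windows"]["n"] == sum(e.success for e in events)

    def test_area_protocol_free_space_positive(self, crw_match, crw_library):
        dataset, _ = crw_match
        res = area_protocol(dataset, crw_library, stride=200)
        assert np.all(res.free_areas > 0)
        assert np.all(res.model_areas >= 0)
        # Voronoi assigns the whole pitch; the model leaves free space
        assert res.voronoi_areas.sum() == pytest.approx(
            7140.0 * len(res.frames), rel=1e-9
        )
        assert res.model_areas.sum() < res.voronoi_areas.sum()
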
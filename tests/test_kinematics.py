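import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import rok
from rok.assignment import RANDOM
from rok.errors import ContractViolationError, InvalidParameterError

from conftest import make_scene


class TestSampleSpeed:
    def test_zero_randomisation_is_exact(self, rng):
        assert rok.sample_speed(24.0, 0.0, rng) == 24.0

    def test_full_randomisation_spans_zero_to_double(self, rng):
        draws = [rok.sample_speed(24.0, 1.0, rng) for _ in range(2000)]
        assert min(draws) >= 0.0 and max(draws) <= 48.0

    def test_mean_matches_uniform_law(self):
        rng = np.random.default_rng(11)
        draws = np.array([rok.sample_speed(24.0, 0.5, rng) for _ in range(100_000)])
        se = 24 * 0.5 / np.sqrt(3) / np.sqrt(draws.size)
        assert abs(draws.mean() - 24.0) < 3 * se

    @given(st.floats(0, 100), st.floats(0, 1))
    def test_bounds_always_hold(self, base, r):
        rng = np.random.default_rng(0)
        v = rok.sample_speed(base, r, rng)
        assert base * (1 - r) - 1e-9 <= v <= base * (1 + r) + 1e-9

    def test_invalid_randomisation_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            rok.sample_speed(24.0, 1.5, rng)


class TestInitPositions:
    def test_empty(self, rng, square_aperture):
        assert rok.init_positions(0, square_aperture.region(), rng).shape == (0, 2)

    def test_uniform_mean_at_center(self):
        rng = np.random.default_rng(3)
        region = rok.ApertureSpec(width=600, height=400).region(800, 600)
        pts = rok.init_positions(10_000, region, rng)
        se_x = region.width / np.sqrt(12) / np.sqrt(len(pts))
        se_y = region.height / np.sqrt(12) / np.sqrt(len(pts))
        assert abs(pts[:, 0].mean() - region.cx) < 3 * se_x
        assert abs(pts[:, 1].mean() - region.cy) < 3 * se_y

    def test_elliptic_containment(self, rng):
        region = rok.ApertureSpec(width=300, height=150, shape=rok.ApertureShape.elliptic).region()
        pts = rok.init_positions(10_000, region, rng)
        assert all(rok.point_in_aperture(x, y, region) for x, y in pts)


class TestRefreshRandomDirection:
    def _state(self, cls=RANDOM):
        return rok.OOBState(x=0, y=0, movement_direction=10, orientation=0, speed=1,
                            movement_class=cls, orientation_class=cls)

    def test_fixed_random_is_identity(self, rng):
        s = self._state()
        assert rok.refresh_random_direction(s, rok.RandomType.fixed_random, rng) is s

    def test_non_random_object_rejected(self, rng):
        with pytest.raises(ContractViolationError):
            rok.refresh_random_direction(self._state("coherent"), rok.RandomType.time_varying, rng)

    def test_reproducible_sequence(self):
        seq1 = [rok.refresh_random_direction(self._state(), rok.RandomType.time_varying,
                                             np.random.default_rng(5)).movement_direction]
        seq2 = [rok.refresh_random_direction(self._state(), rok.RandomType.time_varying,
                                             np.random.default_rng(5)).movement_direction]
        assert seq1 == seq2

    def test_time_varying_directions_uniform(self):
        rng = np.random.default_rng(9)
        s = self._state()
        draws = np.array([
            rok.refresh_random_direction(s, rok.RandomType.time_varying, rng).movement_direction
            for _ in range(10_000)
        ])
        counts, _ = np.histogram(draws, bins=36, range=(0, 360))
        assert stats.chisquare(counts).pvalue > 0.01


class TestStep:
    def test_single_step_displacement(self, rng):
        scene = make_scene(n=1, coherence=1.0, opposite=0.0, direction=0.0, units=rok.Units.pixels,
                           speed=24.0)
        aperture, layer = scene.apertures[0]
        st_ = rok.realize_layer(aperture, layer, rng)
        st_.x[:], st_.y[:] = 400.0, 300.0
        clock = rok.FrameClock(nominal_fps=60)
        rok.step(st_, layer, aperture.region(), clock, rng)
        assert st_.x[0] == pytest.approx(400.0 + 0.4)
        assert st_.y[0] == pytest.approx(300.0)

    def test_one_second_net_displacement_is_three_percent(self, rng):
        scene = make_scene(n=1, coherence=1.0, opposite=0.0, speed=3.0)
        aperture, layer = scene.apertures[0]
        st_ = rok.realize_layer(aperture, layer, rng)
        region = aperture.region()
        st_.x[:], st_.y[:] = region.cx, region.cy
        y0 = st_.y[0]
        clock = rok.FrameClock(nominal_fps=60)
        for _ in range(60):
            clock.tick()
            rok.step(st_, layer, region, clock, rng)
        # direction 90 = screen-up; net displacement 3% of the 600 px width
        assert y0 - st_.y[0] == pytest.approx(0.03 * region.width)

    def test_containment_and_class_conservation_over_animation(self, rng):
        scene = make_scene(n=600, random_movement_type=rok.RandomType.time_varying)
        run = rok.simulate_scene(scene, 120, rng, record=True)
        region = scene.apertures[0][0].region()
        assert all(rok.point_in_aperture(x, y, region) for x, y in zip(run.log.x, run.log.y))
        per_frame = run.log.groupby("frame_index")["movement_class"].value_counts().unstack()
        assert (per_frame.nunique() == 1).all()  # class counts constant across frames

    def test_zero_speed_layer_is_fixed_point(self, rng):
        scene = make_scene(n=30, speed=0.0, coherence=0.0, opposite=0.0,
                           random_movement_type=rok.RandomType.time_varying)
        aperture, layer = scene.apertures[0]
        st_ = rok.realize_layer(aperture, layer, rng)
        x0, y0, d0 = st_.x.copy(), st_.y.copy(), st_.movement_direction.copy()
        clock = rok.FrameClock(nominal_fps=60)
        for _ in range(5):
            clock.tick()
            rok.step(st_, layer, aperture.region(), clock, rng)
        assert np.array_equal(st_.x, x0) and np.array_equal(st_.y, y0)
        assert not np.array_equal(st_.movement_direction, d0)  # headings still refresh

    def test_speed_randomisation_bounds_realized(self, rng):
        scene = make_scene(n=200, speed=3.0, movement_speed_randomisation=0.5)
        aperture, layer = scene.apertures[0]
        st_ = rok.realize_layer(aperture, layer, rng)
        base = rok.to_pixels(3.0, aperture.region())
        assert st_.speed.min() >= base * 0.5 and st_.speed.max() <= base * 1.5


class TestReinsert:
    def _region(self):
        return rok.ApertureSpec(width=400, height=200).region(800, 600)

    def test_rightward_mover_reenters_left_edge(self, rng):
        region = self._region()
        s = rok.OOBState(x=region.x1 + 5, y=region.cy, movement_direction=0, orientation=0,
                         speed=10, movement_class="coherent", orientation_class="coherent")
        out = rok.reinsert(s, region, rng)
        assert out.x == region.x0
        assert region.y0 <= out.y <= region.y1
        assert out.movement_direction == 0 and out.speed == 10

    def test_entry_points_uniform_along_edge(self):
        rng = np.random.default_rng(21)
        region = self._region()
        s = rok.OOBState(x=region.x1 + 5, y=region.cy, movement_direction=0, orientation=0,
                         speed=10, movement_class="coherent", orientation_class="coherent")
        ys = np.array([rok.reinsert(s, region, rng).y for _ in range(10_000)])
        u = (ys - region.y0) / region.height
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_elliptic_entry_on_boundary_and_admissible(self, rng):
        region = rok.ApertureSpec(width=300, height=200, shape=rok.ApertureShape.elliptic).region()
        s = rok.OOBState(x=region.x1 + 5, y=region.cy, movement_direction=45, orientation=0,
                         speed=10, movement_class="coherent", orientation_class="coherent")
        for _ in range(100):
            out = rok.reinsert(s, region, rng)
            a, b = region.width / 2, region.height / 2
            r = ((out.x - region.cx) / a) ** 2 + ((out.y - region.cy) / b) ** 2
            assert r == pytest.approx(1.0, abs=1e-9)


class TestFadeAlpha:
    def test_ramp_values(self):
        region = rok.ApertureSpec(width=200, height=200, fade_out=True).region(800, 600)
        assert rok.fade_alpha(region.cx, region.cy, region) == 1.0
        assert rok.fade_alpha(region.x0, region.cy, region) == 0.0
        # midway through the outer 10% band of the half-extent
        half_band_px = 0.05 * region.width / 2
        assert rok.fade_alpha(region.x0 + half_band_px, region.cy, region) == pytest.approx(0.5)

    def test_alpha_one_everywhere_without_fade(self, rng):
        scene = make_scene(n=100, fade_out=False)
        run = rok.simulate_scene(scene, 5, rng)
        assert (run.log.alpha == 1.0).all()

    def test_fade_scene_has_unit_alpha_interior_only(self, rng):
        scene = make_scene(n=200, fade_out=True)
        aperture, layer = scene.apertures[0]
        st_ = rok.realize_layer(aperture, layer, rng)
        region = aperture.region()
        inner = np.array([region.edge_fraction(x, y) for x, y in zip(st_.x, st_.y)]) >= 0.1
        assert np.all(st_.alpha[inner] == 1.0)
        assert np.all((st_.alpha >= 0) & (st_.alpha <= 1))


class TestFrameClockAndLogs:
    def test_clock_accumulates_nominal_durations(self):
        clock = rok.FrameClock(nominal_fps=60)
        for _ in range(12):
            clock.tick()
        assert clock.frame_index == 12
        assert clock.frame_times_ms == pytest.approx([1000 / 60] * 12)

    def test_log_round_trip_csv_and_jsonl(self, rng, tmp_path):
        scene = make_scene(n=10)
        run = rok.simulate_scene(scene, 4, rng)
        for fmt, name in [("csv", "log.csv"), ("jsonl", "log.jsonl")]:
            path = tmp_path / name
            rok.write_trajectory_log(run.log, path, fmt)
            back = rok.read_trajectory_log(path)
            assert list(back.columns) == list(run.log.columns)
            assert np.allclose(back["x"], run.log["x"])
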
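"""Time stepping, scenarios, density conversions and trajectory I/O."""

import numpy as np
import pytest
from dataclasses import replace

from swarmsim.avoidance import AvoidanceConfig
from swarmsim.core import InsectState, SwarmParams
from swarmsim.noise import NoiseSpec
from swarmsim.simulator import (
    SCENARIOS,
    SimConfig,
    Trajectory,
    build_scenario,
    measure_density,
    polarization,
    read_trajectory,
    run,
    step,
    temperature_to_density,
    write_trajectory,
)


def _free_config(**over):
    """Single-insect config with every force switched off."""
    params = SwarmParams(
        gamma=0.0, scale=1.0, gain=0.0, chi_rep=0, r_rep=0, chi_ali=0,
        r_ali=0, chi_att=0, r_att=0, chi_res=0, r_res=0,
    )
    kw = dict(
        n_insects=1,
        params=params,
        noise=NoiseSpec(kind="curl", scale=1.0, gain=0.0, seed=0),
        boundary_mode="none",
        avoidance=AvoidanceConfig(max_speed=100.0),
        n_frames=10,
        seed=0,
    )
    kw.update(over)
    return SimConfig(**kw)


class TestStep:
    def test_free_insect_drifts_in_straight_line(self, rng):
        cfg = _free_config()
        v0 = np.array([1.0, -0.5, 0.25])
        states = [InsectState(position=np.zeros(3), velocity=v0)]
        for k in range(1, 21):
            states = step(states, cfg, rng, frame=k - 1)
            assert np.allclose(states[0].position, v0 * k * cfg.dt, atol=1e-12)
            assert np.allclose(states[0].velocity, v0)

    def test_friction_decays_speed_toward_zero(self, rng):
        gamma = 2.0
        cfg = _free_config(params=SwarmParams(
            gamma=gamma, scale=1.0, gain=0.0, chi_rep=0, r_rep=0, chi_ali=0,
            r_ali=0, chi_att=0, r_att=0, chi_res=0, r_res=0,
        ))
        v0 = 3.0
        states = [InsectState(position=np.zeros(3), velocity=[v0, 0, 0])]
        speeds = [v0]
        for k in range(60):
            states = step(states, cfg, rng, frame=k)
            speeds.append(float(np.linalg.norm(states[0].velocity)))
        assert all(b < a for a, b in zip(speeds, speeds[1:]))
        # quadratic drag closed form v(t) = v0 / (1 + gamma v0 t), Euler
        # discretization error at dt = 1/60 stays small
        t = 60 * cfg.dt
        assert speeds[-1] == pytest.approx(v0 / (1 + gamma * v0 * t), rel=0.05)

    def test_repulsion_pair_separates_in_one_step(self, rng, params):
        cfg = _free_config(n_insects=2, params=params)
        d0 = 0.5 * params.r_rep
        states = [
            InsectState(position=np.zeros(3), velocity=np.zeros(3)),
            InsectState(position=[d0, 0, 0], velocity=np.zeros(3)),
        ]
        # hand-evaluated Euler step: each feels chi_rep away from the other,
        # v = chi_rep * dt, so separation grows by 2 chi_rep dt^2
        new = step(states, cfg, rng)
        sep = np.linalg.norm(new[1].position - new[0].position)
        assert sep > d0
        assert sep == pytest.approx(d0 + 2 * params.chi_rep * cfg.dt**2, rel=1e-9)

    def test_nonfinite_force_aborts_with_named_term(self, rng):
        cfg = _free_config()
        bad = NoiseSpec(kind="curl", scale=1.0, gain=0.0, seed=0)
        bad.sample = lambda *a, **k: np.full((1, 3), np.nan)
        cfg.noise = bad
        states = [InsectState(position=np.zeros(3), velocity=np.zeros(3))]
        with pytest.raises(FloatingPointError, match="inherent-noise"):
            step(states, cfg, rng)


class TestRun:
    def test_single_frame_is_initial_state_only(self):
        cfg = build_scenario("midge_box", n_insects=5, n_frames=1, seed=1)
        traj = run(cfg)
        assert traj.positions.shape == (1, 5, 3)

    def test_deterministic_under_seed(self):
        cfg = build_scenario("midge_box", n_insects=10, n_frames=30, seed=4)
        assert np.array_equal(run(cfg).positions, run(cfg).positions)

    def test_seeds_differ(self):
        a = run(build_scenario("midge_box", n_insects=10, n_frames=30, seed=4))
        b = run(build_scenario("midge_box", n_insects=10, n_frames=30, seed=5))
        assert not np.allclose(a.positions, b.positions)

    def test_reflecting_box_contains_swarm(self):
        cfg = build_scenario("midge_box", n_insects=20, n_frames=100, seed=2)
        traj = run(cfg)
        assert traj.positions.min() >= 0.0
        assert traj.positions.max() <= 20.0

    def test_swarm_center_hardly_moves(self):
        # stationary swarming: frame-to-frame center-of-mass displacement is
        # small relative to the swarm radius
        cfg = build_scenario("midge_box", n_insects=100, n_frames=300, seed=1)
        traj = run(cfg)
        com = traj.positions.mean(axis=1)
        com_step = np.linalg.norm(np.diff(com, axis=0), axis=1).mean()
        radius = np.linalg.norm(
            traj.positions - com[:, None, :], axis=2
        ).mean()
        assert com_step < 0.05 * radius


class TestScenarios:
    def test_all_scenarios_build(self):
        for name in SCENARIOS:
            cfg = build_scenario(name)
            assert cfg.params.r_att >= cfg.params.r_ali >= cfg.params.r_rep

    @pytest.mark.parametrize("name", SCENARIOS)
    def test_every_scenario_simulates(self, name):
        cfg = build_scenario(name, n_insects=10, n_frames=8, seed=1)
        traj = run(cfg)
        assert traj.positions.shape == (8, 10, 3)

    def test_escape_column(self):
        cfg = build_scenario("escape")
        assert cfg.params.chi_res == 20.0
        assert cfg.params.r_res == 8.0
        assert cfg.stimuli[0].kind == 1  # predator

    def test_migration_geometry(self):
        cfg = build_scenario("migration")
        assert cfg.n_insects == 2000
        assert np.allclose(cfg.box[:, 1] - cfg.box[:, 0], [24.0, 5.0, 0.5])
        assert cfg.boundary_mode == "none"
        assert cfg.stimuli[0].kind == 0  # pursuit target

    def test_single_agent_override(self):
        cfg = build_scenario("midge_box", n_insects=1)
        assert cfg.n_insects == 1
        run(replace(cfg, n_frames=3))  # still simulates

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("antswarm")

    def test_phase_transition_has_schedule(self):
        cfg = build_scenario("phase_transition")
        assert cfg.schedule is not None
        assert "gain" in cfg.schedule.ramps
        assert "chi_ali" in cfg.schedule.ramps


class TestTemperatureDensity:
    def test_cold_clamps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert temperature_to_density(0.0) == 0.0

    def test_peak_temperature(self):
        t_star = 4.7643 / (2 * 0.1073)
        n_star = temperature_to_density(t_star)
        for t in np.linspace(10, 35, 101):
            assert n_star >= temperature_to_density(t) - 1e-12

    def test_parabola_symmetry(self):
        t_star = 4.7643 / (2 * 0.1073)
        for dt_ in (1.0, 3.0, 5.0):
            assert temperature_to_density(t_star + dt_) == pytest.approx(
                temperature_to_density(t_star - dt_), abs=1e-9
            )


class TestMeasureDensity:
    def test_aggregation_worked_example(self):
        # fixed reference volume anchored so that 500 insects give
        # 9,469.7 per cubic meter; density is proportional to count
        v0 = 500 / 9469.7
        t500 = Trajectory(np.zeros((3, 500, 3)), dt=1 / 60)
        t3000 = Trajectory(np.zeros((3, 3000, 3)), dt=1 / 60)
        assert measure_density(t500, v0)[0] == pytest.approx(9469.7)
        assert measure_density(t3000, v0)[0] == pytest.approx(56818.2, abs=0.05)

    def test_empty_swarm(self):
        t = Trajectory(np.zeros((2, 0, 3)), dt=1 / 60)
        assert np.all(measure_density(t, 1.0) == 0.0)

    def test_bad_volume(self):
        t = Trajectory(np.zeros((2, 1, 3)), dt=1 / 60)
        with pytest.raises(ValueError):
            measure_density(t, 0.0)


class TestPolarization:
    def test_fully_aligned(self):
        v = np.tile([1.0, 2.0, 0.0], (10, 1))
        assert polarization(v) == pytest.approx(1.0)

    def test_antiparallel_pairs_cancel(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]] * 5)
        assert polarization(v) == pytest.approx(0.0, abs=1e-12)

    def test_all_at_rest(self):
        assert polarization(np.zeros((5, 3))) == 0.0


class TestTrajectoryIO:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        traj = Trajectory(rng.normal(0, 10, (4, 3, 3)), dt=1 / 60)
        p = tmp_path / "t.tsv"
        write_trajectory(traj, p)
        back = read_trajectory(p)
        assert np.array_equal(back.positions, traj.positions)
        assert back.dt == traj.dt

    def test_row_count(self, tmp_path):
        traj = Trajectory(np.zeros((2, 2, 3)), dt=0.1)
        p = tmp_path / "t.tsv"
        write_trajectory(traj, p)
        data_rows = [
            line for line in p.read_text().splitlines()
            if line and not line.startswith("#") and not line.startswith("frame")
        ]
        assert len(data_rows) == 4

    def test_missing_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("frame\tinsect\tx\ty\tz\n0\t0\t1.0\t2.0\t3.0\n0\t1\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_trajectory(p)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("frame\tinsect\tx\ty\tz\n0\t0\tapple\t2.0\t3.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_trajectory(p)

    def test_incomplete_grid_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("frame\tinsect\tx\ty\tz\n0\t0\t1\t2\t3\n1\t1\t1\t2\t3\n")
        with pytest.raises(ValueError, match="expected"):
            read_trajectory(p)


class TestEscapeResponse:
    def test_swarm_disperses_then_reaggregates(self):
        cfg = build_scenario("escape", n_insects=60, n_frames=400, seed=3)
        traj = run(cfg)
        stim = cfg.stimuli[0]
        pred = stim.position
        dist = np.linalg.norm(traj.positions - pred, axis=2).mean(axis=1)
        # activation window is [150, 300): within 50 frames of activation
        # the mean distance to the predator grows monotonically at the
        # 5-frame resolution; the first ~10 frames are inertial lag (the
        # response force needs about 0.17 s to reverse the inward velocities)
        window = dist[stim.start_frame + 10:stim.start_frame + 50]
        blocks = window.reshape(8, 5).mean(axis=1)
        assert np.all(np.diff(blocks) > 0)
        assert dist[stim.start_frame + 50] > dist[stim.start_frame]
        # after the danger disappears the swarm contracts again
        radius = np.linalg.norm(
            traj.positions - traj.positions.mean(axis=1, keepdims=True), axis=2
        ).mean(axis=1)
        assert radius[-1] < radius[stim.end_frame]


class TestNoiseTypeEffect:
    def test_white_noise_produces_rougher_trajectories_than_curl(self):
        # white noise decorrelates step to step while the Curl field is
        # smooth in space, so at matched gain the Cartesian jerk must
        # fluctuate far more under white noise; a single insect isolates the
        # noise force from interaction effects
        from swarmsim.metrics import compute_metric

        base = build_scenario("midge_box", n_insects=1, n_frames=400, seed=6)
        jerk_var = {}
        for kind in ("white", "curl"):
            cfg = replace(base)
            cfg.noise = NoiseSpec(kind=kind, scale=base.params.scale,
                                  gain=base.params.gain, seed=6)
            traj = run(cfg)
            jerk_var[kind] = compute_metric("mu", traj).values.var()
        assert jerk_var["white"] > jerk_var["curl"]
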
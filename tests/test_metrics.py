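"""The seven kinematic metrics and the entropy-weighted evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmsim.estimation import generate_fixture
from swarmsim.metrics import (
    METRICS,
    DiscretePDF,
    compare_models,
    compute_metric,
    discrete_pdf,
    energy_term,
    entropy_weights,
    evaluate,
    evaluation_score,
    zscore,
)
from swarmsim.simulator import Trajectory


class TestMetrics:
    def test_straight_lines_have_zero_rotation_and_jerk(self):
        traj = generate_fixture("straightline", n_insects=5, n_frames=20, seed=0)
        for m in ("omega", "alpha", "mu"):
            vals = compute_metric(m, traj).values
            # arccos noise near 1 amplifies to ~1e-6 rad/s at dt = 1/60
            assert np.allclose(vals, 0.0, atol=1e-3)

    def test_straight_line_speed_constant(self):
        traj = generate_fixture("straightline", n_insects=3, n_frames=10, seed=0)
        v = compute_metric("v", traj).values.reshape(9, 3)
        assert np.allclose(v, v[0], atol=1e-9)

    def test_rotating_velocity_quarter_turn(self):
        # velocity direction turns 90 degrees per frame at dt = 1
        n_frames = 10
        pos = np.zeros((n_frames, 1, 3))
        v = np.array([1.0, 0.0, 0.0])
        rot = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])
        for f in range(1, n_frames):
            pos[f, 0] = pos[f - 1, 0] + v
            v = rot @ v
        traj = Trajectory(pos, dt=1.0)
        omega = compute_metric("omega", traj).values
        assert np.allclose(omega, np.pi / 2)
        alpha = compute_metric("alpha", traj).values
        assert np.allclose(alpha, 0.0, atol=1e-12)

    def test_two_body_distance_and_velocity_difference(self):
        traj = generate_fixture("two_body", n_frames=50, separation=2.0,
                                speeds=(3.0, 1.0))
        d = compute_metric("d", traj).values
        assert np.allclose(d, 2.0, atol=1e-9)
        eta = compute_metric("eta", traj).values.reshape(-1, 2)
        # faster insect: (1 - 3)/2 = -1; slower: (3 - 1)/2 = +1
        # (finite-difference speeds are chords, hence the loose tolerance)
        assert np.allclose(eta[:, 0], -1.0, atol=1e-3)
        assert np.allclose(eta[:, 1], +1.0, atol=1e-3)

    def test_lattice_is_static(self):
        traj = generate_fixture("lattice", n_insects=8, n_frames=5)
        assert np.allclose(compute_metric("v", traj).values, 0.0)
        # a static insect has no direction: every omega sample is skipped
        assert compute_metric("omega", traj).values.size == 0

    def test_metric_needs_enough_frames(self):
        traj = Trajectory(np.zeros((2, 2, 3)), dt=1.0)
        with pytest.raises(ValueError):
            compute_metric("alpha", traj)

    def test_unknown_metric(self):
        traj = Trajectory(np.zeros((5, 2, 3)), dt=1.0)
        with pytest.raises(ValueError):
            compute_metric("curvature", traj)


class TestZScore:
    def test_two_point_example(self):
        assert np.allclose(zscore(np.array([0.0, 2.0])), [-1.0, 1.0])

    def test_already_standardized_unchanged(self, rng):
        x = rng.normal(0, 1, 5000)
        x = (x - x.mean()) / x.std()
        assert np.allclose(zscore(x), x, atol=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(3, 2, 100)
        assert np.allclose(zscore(x), zscore(5.0 * x - 7.0), atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore(np.ones(10))

    def test_output_moments(self, rng):
        z = zscore(rng.exponential(2.0, 1000))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9


class TestDiscretePDF:
    def test_single_bin_occupancy(self):
        # all S samples in one bin: that bin's density is M/(u2-u1)
        pdf = discrete_pdf(np.full(40, 0.55), m=10, interval=(0.0, 1.0))
        assert pdf.densities[5] == pytest.approx(10.0)
        assert np.count_nonzero(pdf.densities) == 1

    def test_uniform_converges_to_flat(self, rng):
        pdf = discrete_pdf(rng.random(100_000), m=20, interval=(0.0, 1.0))
        assert np.allclose(pdf.densities, 1.0, atol=0.05)

    def test_single_bin_m1(self, rng):
        pdf = discrete_pdf(rng.normal(0, 1, 100), m=1, interval=(-4.0, 4.0))
        assert pdf.densities[0] == pytest.approx(1.0 / 8.0)

    def test_out_of_range_samples_clipped(self):
        pdf = discrete_pdf(np.array([-5.0, 0.5, 5.0]), m=4, interval=(0.0, 1.0))
        assert pdf.integral() == pytest.approx(1.0)
        assert pdf.densities[0] > 0 and pdf.densities[-1] > 0

    @given(st.integers(1, 40), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_always_integrates_to_one(self, m, n):
        rng = np.random.default_rng(m * 1000 + n)
        samples = rng.normal(0, 2, n)
        lo, hi = samples.min() - 0.1, samples.max() + 0.1
        pdf = discrete_pdf(samples, m=m, interval=(lo, hi))
        assert pdf.integral() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pdf.densities >= 0)


class TestEnergyTerm:
    def test_identical_pdfs_zero(self, rng):
        x = rng.normal(0, 1, 500)
        q = discrete_pdf(x, 20, (-4, 4))
        assert energy_term(q, q) == 0.0

    def test_disjoint_single_bin_pdfs(self):
        m, u1, u2 = 10, 0.0, 1.0
        qa = discrete_pdf(np.full(5, 0.05), m, (u1, u2))
        qb = discrete_pdf(np.full(5, 0.95), m, (u1, u2))
        assert energy_term(qa, qb) == pytest.approx(2 * m / (u2 - u1))

    def test_normalization_arithmetic(self):
        q = DiscretePDF(0.0, 1.0, np.array([1.0]))
        # raw = 0 here; use explicit raw via two constructed pdfs
        qa = discrete_pdf(np.array([0.1]), 2, (0, 1))
        qb = discrete_pdf(np.array([0.9]), 2, (0, 1))
        raw = float(np.abs(qa.densities - qb.densities).sum())
        assert energy_term(qa, qb, p1=0.3, p2=0.5) == pytest.approx((raw - 0.3) / 0.5)

    def test_probability_mass_variant_scales_by_bin_width(self, rng):
        a = discrete_pdf(rng.normal(0, 1, 300), 20, (-4.0, 4.0))
        b = discrete_pdf(rng.normal(0.5, 2, 300), 20, (-4.0, 4.0))
        dens = energy_term(a, b)
        prob = energy_term(a, b, on="probabilities")
        assert prob == pytest.approx(dens * 8.0 / 20.0)

    def test_symmetry(self, rng):
        a = discrete_pdf(rng.normal(0, 1, 300), 15, (-4, 4))
        b = discrete_pdf(rng.normal(0.5, 2, 300), 15, (-4, 4))
        assert energy_term(a, b) == energy_term(b, a)

    def test_mismatched_binning_rejected(self, rng):
        a = discrete_pdf(rng.random(10), 5, (0, 1))
        b = discrete_pdf(rng.random(10), 6, (0, 1))
        with pytest.raises(ValueError, match="share"):
            energy_term(a, b)


class TestEvaluationScore:
    def test_perfect_match(self):
        e = {k: 0.0 for k in METRICS}
        w = {k: 1.0 / 7 for k in METRICS}
        assert evaluation_score(e, w) == pytest.approx(1.0)

    def test_unit_energies(self):
        e = {k: 1.0 for k in METRICS}
        w = {k: 1.0 / 7 for k in METRICS}
        assert evaluation_score(e, w) == pytest.approx(0.0)

    def test_arithmetic(self):
        e = dict(zip(METRICS, [0.2, 0.4, 0, 0, 0, 0, 0]))
        w = dict(zip(METRICS, [0.5, 0.5, 0, 0, 0, 0, 0]))
        assert evaluation_score(e, w) == pytest.approx(0.7)

    def test_key_mismatch(self):
        with pytest.raises(ValueError):
            evaluation_score({"v": 0.0}, {"a": 1.0})


class TestEntropyWeights:
    def test_hand_example_two_identical_columns(self):
        w, p1, p2 = entropy_weights(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(w, [0.5, 0.5])
        assert np.allclose(p1, [0.0, 0.0])
        assert np.allclose(p2, [1.0, 1.0])

    def test_single_support_column_has_zero_entropy(self):
        # col 0: one model stands out fully (r = 1 vs 0) -> e = 0 -> the
        # pre-normalization weight 1 - e is maximal
        x = np.array([[0.0, 0.3], [1.0, 0.5], [1.0, 0.4]])
        w, _, _ = entropy_weights(x)
        assert w[0] > w[1]
        # recompute e for col 0 by hand: g = (1, 0, 0) -> entropy 0
        assert w[0] == pytest.approx((1 - 0.0) / ((1 - 0.0) + (1 - _col_entropy(x[:, 1]))))

    def test_constant_column_gets_zero_weight(self):
        x = np.array([[0.5, 0.1], [0.5, 0.9]])
        w, _, p2 = entropy_weights(x)
        assert w[0] == 0.0
        assert w[1] == pytest.approx(1.0)
        assert p2[0] == 0.0

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="non-discriminating"):
            entropy_weights(np.ones((3, 4)))

    def test_weights_sum_to_one_and_nonnegative(self, rng):
        for _ in range(50):
            x = rng.random((rng.integers(2, 8), rng.integers(2, 9)))
            w, p1, p2 = entropy_weights(x)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w >= 0)
            assert np.allclose(p1, x.min(axis=0))

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            entropy_weights(np.array([[1.0, 2.0]]))


def _col_entropy(col):
    xn = (col - col.min()) / (col.max() - col.min())
    r = 1 - xn
    g = r / r.sum()
    terms = np.where(g > 0, g * np.log(np.where(g > 0, g, 1)), 0)
    return -terms.sum() / np.log(len(col))


class TestEvaluate:
    def test_identity_scores_one(self):
        traj = generate_fixture("swarmlike", n_insects=10, n_frames=60,
                                seed=3, burn_in=30)
        res = evaluate(traj, traj)
        assert all(e == 0.0 for e in res.energies.values())
        assert res.score == pytest.approx(1.0)

    def test_weights_default_uniform(self):
        traj = generate_fixture("swarmlike", n_insects=8, n_frames=50,
                                seed=3, burn_in=20)
        res = evaluate(traj, traj)
        assert sum(res.weights.values()) == pytest.approx(1.0)


class TestCompareModels:
    def _fits(self, energies_by_model, counter=None):
        fits = {}
        for name, e in energies_by_model.items():
            def fit(weights, p1, p2, _e=e, _n=name):
                if counter is not None:
                    counter[_n] = counter.get(_n, 0) + 1
                return dict(zip(METRICS, _e))
            fits[name] = fit
        return fits

    def test_max_iter_one_single_fit_each(self):
        counter = {}
        fits = self._fits(
            {"a": [0.1] * 7, "b": [0.9, 0.1, 0.4, 0.3, 0.2, 0.6, 0.8]},
            counter,
        )
        ref = Trajectory(np.zeros((3, 2, 3)), dt=1.0)
        compare_models(fits, ref, max_iter=1)
        assert counter == {"a": 1, "b": 1}

    def test_identical_models_score_equally(self):
        fits = self._fits({
            "a": [0.3, 0.5, 0.2, 0.7, 0.4, 0.6, 0.1],
            "b": [0.3, 0.5, 0.2, 0.7, 0.4, 0.6, 0.1],
            "c": [0.9, 0.8, 0.9, 0.9, 0.8, 0.9, 0.9],
        })
        ref = Trajectory(np.zeros((3, 2, 3)), dt=1.0)
        results, weights, _ = compare_models(fits, ref)
        assert results["a"].score == pytest.approx(results["b"].score)
        assert results["a"].score > results["c"].score

    def test_fixed_energies_converge_in_two_iterations(self):
        fits = self._fits({
            "a": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
            "b": [0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1],
        })
        ref = Trajectory(np.zeros((3, 2, 3)), dt=1.0)
        _, _, history = compare_models(fits, ref, max_iter=10, tol=1e-3)
        assert len(history) == 2  # second pass reproduces the weights exactly

    def test_needs_two_models(self):
        ref = Trajectory(np.zeros((3, 2, 3)), dt=1.0)
        with pytest.raises(ValueError):
            compare_models({"only": lambda w, p1, p2: {}}, ref)
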
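import json

import numpy as np
import pytest

from helpers_oracle import joint_gaussian_loglik
from skigears import (GEARS, AccelerometerStream, GearClassModel,
                      GearClassifier, GearMarkovModel, NormalizedCycle,
                      PreprocessConfig, SimulationConfig, extract_cycles,
                      fit_markov_gaussian, simulate_trial, train_classifier)
from skigears.preprocess import CycleSegment
from skigears.exceptions import (CoverageError, InsufficientDataError,
                                 ModelIntegrityError, ValidationError)


def toy_cycles(rng, n_cycles, n_steps=3, scale=1.0, shift=0.0):
    segs = [CycleSegment(i * 1.0, i * 1.0 + 1.0) for i in range(n_cycles)]
    return [NormalizedCycle(shift + scale * rng.normal(size=(n_steps, 3)), s)
            for s in segs]


def mean_trajectory_model(gear, means, cov_scale=1.0):
    """Chain whose mean trajectory is `means` with A_t = 0 and isotropic covs."""
    T = len(means)
    eye = np.eye(3)
    return GearClassModel(
        gear=gear, mu1=means[0], S1=cov_scale * eye,
        A=np.zeros((T - 1, 3, 3)), b=np.asarray(means[1:], float),
        Q=np.repeat(cov_scale * eye[None], T - 1, axis=0),
    )


class TestFitMarkovGaussian:
    def test_two_identical_cycles_give_pure_ridge_covariances(self):
        vals = np.arange(30.0).reshape(10, 3)
        cycles = [NormalizedCycle(vals, CycleSegment(0, 1)),
                  NormalizedCycle(vals, CycleSegment(1, 2))]
        m = fit_markov_gaussian(cycles, "G3", ridge=1e-3)
        np.testing.assert_allclose(m.S1, 1e-3 * np.eye(3), atol=1e-12)
        np.testing.assert_allclose(m.Q, np.repeat(1e-3 * np.eye(3)[None], 9, 0),
                                   atol=1e-10)
        np.testing.assert_allclose(m.mu1, vals[0])

    def test_single_cycle_rejected(self):
        cyc = NormalizedCycle(np.zeros((5, 3)), CycleSegment(0, 1))
        with pytest.raises(InsufficientDataError):
            fit_markov_gaussian([cyc], "G2L")

    def test_mismatched_step_counts_rejected(self, rng):
        cycles = toy_cycles(rng, 2, n_steps=4) + toy_cycles(rng, 1, n_steps=5)
        with pytest.raises(ValidationError):
            fit_markov_gaussian(cycles, "G2L")

    def test_step_mean_recovery_from_known_chain(self, rng):
        # v_t = 0.5 v_{t-1} + b_t + noise, with b_t chosen so the implied
        # step means follow a known template; 200 cycles, isotropic 0.01 cov
        T, n = 40, 200
        steps = np.arange(T)
        truth = np.column_stack([np.sin(steps / 6), np.cos(steps / 9),
                                 steps / T])
        A = 0.5 * np.eye(3)
        V = np.empty((n, T, 3))
        V[:, 0] = truth[0] + 0.1 * rng.normal(size=(n, 3))
        for t in range(1, T):
            b = truth[t] - 0.5 * truth[t - 1]
            V[:, t] = V[:, t - 1] @ A.T + b + 0.1 * rng.normal(size=(n, 3))
        cycles = [NormalizedCycle(v, CycleSegment(0, 1)) for v in V]
        m = fit_markov_gaussian(cycles, "G3", ridge=1e-6)
        # implied step means of the fitted chain
        means = np.empty((T, 3))
        means[0] = m.mu1
        for t in range(1, T):
            means[t] = m.A[t - 1] @ means[t - 1] + m.b[t - 1]
        # marginal variance recursion gives the standard error per step
        var = np.empty(T)
        var[0] = 0.01
        for t in range(1, T):
            var[t] = 0.25 * var[t - 1] + 0.01
        se = np.sqrt(var / n)[:, None]
        within = np.abs(means - truth) <= 3 * se
        assert within.mean() >= 0.95


class TestLogLikelihood:
    def test_closed_form_on_mean_trajectory(self, rng):
        means = rng.normal(size=(100, 3))
        m = mean_trajectory_model("G3", means)
        ll = m.log_likelihood(NormalizedCycle(means, CycleSegment(0, 1)))
        assert ll == pytest.approx(-150.0 * np.log(2 * np.pi), abs=1e-9)

    def test_chain_equals_joint_gaussian_oracle(self, rng):
        m = fit_markov_gaussian(toy_cycles(rng, 30), "G2L", ridge=1e-2)
        for v in rng.normal(size=(10, 3, 3)):
            assert m.log_likelihood(v) == pytest.approx(
                joint_gaussian_loglik(m, v), abs=1e-8)

    def test_deviation_scaling_decreases_likelihood(self, rng):
        means = rng.normal(size=(20, 3))
        m = mean_trajectory_model("G4L", means)
        dev = rng.normal(size=(20, 3))
        lls = [m.log_likelihood(means + k * dev) for k in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_non_pd_covariance_detected(self):
        m = mean_trajectory_model("G3", np.zeros((4, 3)))
        m.S1 = -np.eye(3)
        with pytest.raises(ModelIntegrityError):
            m.log_likelihood(np.zeros((4, 3)))


class TestClassifier:
    def test_cycle_on_mean_trajectory_classified_correctly(
            self, trained_classifier):
        g3 = trained_classifier.models["G3"]
        means = np.empty((g3.n_steps, 3))
        means[0] = g3.mu1
        for t in range(1, g3.n_steps):
            means[t] = g3.A[t - 1] @ means[t - 1] + g3.b[t - 1]
        pred = trained_classifier.classify_cycle(
            NormalizedCycle(means, CycleSegment(0, 1.4)))
        assert pred.gear == "G3"
        assert all(pred.loglik["G3"] > pred.loglik[g]
                   for g in GEARS if g != "G3")

    def test_exact_ties_break_to_canonical_order(self, rng):
        means = rng.normal(size=(5, 3))
        models = {g: mean_trajectory_model(g, means + 10.0) for g in GEARS}
        # G2R and G4L share an identical (closer) model
        for g in ("G2R", "G4L"):
            models[g] = mean_trajectory_model(g, means)
        clf = GearClassifier(models, PreprocessConfig(n_steps=5))
        pred = clf.classify_cycle(NormalizedCycle(means, CycleSegment(0, 1)))
        assert pred.gear == "G2R"
        assert pred.loglik["G2R"] == pred.loglik["G4L"]

    def test_argmax_agrees_with_joint_gaussian_oracle(self, rng):
        clfs = {g: fit_markov_gaussian(toy_cycles(rng, 25, shift=i), g,
                                       ridge=1e-2)
                for i, g in enumerate(GEARS)}
        clf = GearClassifier(clfs, PreprocessConfig(n_steps=3))
        for v in rng.normal(scale=2.0, size=(20, 3, 3)):
            pred = clf.classify_cycle(NormalizedCycle(v, CycleSegment(0, 1)))
            oracle = max(GEARS,
                         key=lambda g: joint_gaussian_loglik(clfs[g], v))
            assert pred.gear == oracle

    def test_missing_gear_raises_coverage_error(self, rng):
        cycles = {g: toy_cycles(rng, 5) for g in GEARS if g != "G4R"}
        with pytest.raises(CoverageError, match="G4R"):
            GearMarkovModel(cycles)

    def test_training_is_deterministic(self, rng):
        cycles = {g: toy_cycles(rng, 6) for g in GEARS}
        a = train_classifier(cycles, preprocess_config=PreprocessConfig(n_steps=3))
        b = train_classifier(cycles, preprocess_config=PreprocessConfig(n_steps=3))
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_serialization_roundtrip(self, tmp_path, trained_classifier):
        p = tmp_path / "model.json"
        trained_classifier.save(p)
        back = GearClassifier.load(p)
        assert json.dumps(back.to_dict()) == json.dumps(
            trained_classifier.to_dict())
        assert back.regime == trained_classifier.regime

    def test_summary_lists_all_gears(self, trained_classifier):
        s = trained_classifier.summary()
        assert all(g in s for g in GEARS)
        assert "ridge" in s


class TestClassifyStream:
    def test_constant_stream_gives_no_predictions(self, trained_classifier):
        t = np.arange(0, 30, 1 / 80)
        s = AccelerometerStream(t, np.zeros_like(t), np.full_like(t, 9.81),
                                np.zeros_like(t))
        assert trained_classifier.classify_stream(s) == []

    def test_prediction_count_matches_segments(self, trained_classifier):
        from skigears import segment_cycles
        stream, _ = simulate_trial("G2R", 12, SimulationConfig(seed=7))
        preds = trained_classifier.classify_stream(stream)
        segs = segment_cycles(stream, trained_classifier.preprocess_config)
        assert len(preds) == len(segs) > 0
        starts = [p.segment.start for p in preds]
        assert starts == sorted(starts)

    def test_time_shift_invariance(self, trained_classifier):
        stream, _ = simulate_trial("G4R", 10, SimulationConfig(seed=8))
        a = trained_classifier.classify_stream(stream)
        b = trained_classifier.classify_stream(stream.shifted(123.5))
        assert [p.gear for p in a] == [p.gear for p in b]

    def test_own_gear_likelihood_beats_mirror_gear(self, trained_classifier):
        stream, _ = simulate_trial("G2L", 20, SimulationConfig(seed=9))
        cycles = extract_cycles(stream,
                                trained_classifier.preprocess_config)
        m_l = trained_classifier.models["G2L"]
        m_r = trained_classifier.models["G2R"]
        V = np.stack([c.values for c in cycles])
        assert np.all(m_l.log_likelihood_many(V) > m_r.log_likelihood_many(V))


class TestConsistency:
    def test_resubstitution_accuracy_is_perfect(self, trained_classifier):
        # templates are separated by far more than the smoothed noise level
        cycles = {}
        for i, g in enumerate(GEARS):
            stream, _ = simulate_trial(g, 50, SimulationConfig(seed=101 + i))
            cycles[g] = extract_cycles(stream)
        for g, cyc in cycles.items():
            preds = trained_classifier.classify_cycles(cyc)
            assert all(p.gear == g for p in preds)

    def test_more_training_cycles_reduce_step_mean_error(self, rng):
        T = 30
        steps = np.arange(T)
        truth = np.column_stack([np.sin(steps / 5), np.cos(steps / 7),
                                 steps / T])
        A = 0.5 * np.eye(3)

        def mse(n, seed):
            r = np.random.default_rng(seed)
            V = np.empty((n, T, 3))
            V[:, 0] = truth[0] + 0.1 * r.normal(size=(n, 3))
            for t in range(1, T):
                b = truth[t] - 0.5 * truth[t - 1]
                V[:, t] = V[:, t - 1] @ A.T + b + 0.1 * r.normal(size=(n, 3))
            m = fit_markov_gaussian(
                [NormalizedCycle(v, CycleSegment(0, 1)) for v in V], "G3",
                ridge=1e-6)
            means = np.empty((T, 3))
            means[0] = m.mu1
            for t in range(1, T):
                means[t] = m.A[t - 1] @ means[t - 1] + m.b[t - 1]
            return ((means - truth) ** 2).mean()

        m50 = np.mean([mse(50, 600 + s) for s in range(20)])
        m500 = np.mean([mse(500, 600 + s) for s in range(20)])
        assert m500 < m50
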
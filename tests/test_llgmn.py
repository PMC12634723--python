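"""LLGMN classifier: expansion, posterior, training, stream segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from mmdtkit import llgmn, synth
from mmdtkit.llgmn import (
    LlgmnModel,
    MotionLabelSeries,
    classify_motion,
    expand_input,
    expanded_dim,
    forward,
    gaussian_bayes_weights,
    total_hold_time,
    train,
)


class TestExpandInput:
    def test_one_dimensional(self):
        assert np.allclose(expand_input(np.array([3.0])), [1, 3, 9])

    def test_zero_vector(self):
        assert np.allclose(expand_input(np.zeros(2)), [1, 0, 0, 0, 0, 0])

    def test_eight_dim_length(self):
        assert expand_input(np.arange(8.0)).shape == (45,)
        assert expanded_dim(8) == 45

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            expand_input(np.array([1.0, np.nan]))


class TestForward:
    def test_zero_weights_uniform_posterior(self):
        model = LlgmnModel.zeros(input_dim=8)
        assert np.allclose(forward(model, np.zeros(8)), [0.5, 0.5])

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(2, 3, expanded_dim(4)))
        model = LlgmnModel(2, 3, 4, w)
        x = rng.normal(size=4)
        base = forward(model, x)
        # adding the same constant to every (class, component) bias weight
        # shifts all scores equally (the expanded bias feature is 1)
        w2 = w.copy()
        w2[:, :, 0] += 7.3
        assert np.allclose(forward(LlgmnModel(2, 3, 4, w2), x), base, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward(LlgmnModel.zeros(input_dim=8), np.zeros(5))

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=60)
    def test_posterior_normalized_for_arbitrary_weights(self, seed):
        rng = np.random.default_rng(seed)
        m, k, d = int(rng.integers(2, 4)), int(rng.integers(1, 3)), int(rng.integers(1, 6))
        model = LlgmnModel(m, k, d, rng.normal(scale=2, size=(m, k, expanded_dim(d))),
                           classes=tuple(f"c{i}" for i in range(m)))
        p = forward(model, rng.normal(size=d))
        assert np.all(p >= 0) and np.all(p <= 1)
        assert abs(p.sum() - 1.0) < 1e-9


class TestBayesOracle:
    def test_matches_brute_force_gaussian_posterior(self):
        """Analytically constructed weights reproduce the Bayes posterior.

        The log of a Gaussian density is a quadratic form, hence exactly
        representable on the expanded features; the network softmax must
        then equal direct density evaluation.
        """
        rng = np.random.default_rng(7)
        d = 3
        means = [rng.normal(size=d), rng.normal(size=d) + 2.0]
        covs = []
        for _ in range(2):
            a = rng.normal(size=(d, d))
            covs.append(a @ a.T + np.eye(d))
        model = gaussian_bayes_weights(means, covs)
        for _ in range(200):
            x = rng.normal(scale=2, size=d)
            dens = np.array([multivariate_normal.pdf(x, mean=m, cov=c)
                             for m, c in zip(means, covs)])
            bayes = dens / dens.sum()
            assert np.max(np.abs(forward(model, x) - bayes)) < 1e-6


class TestTrain:
    def test_linearly_separable_reaches_full_accuracy(self):
        samples = ([(np.array([1.0]), "hold")] * 10
                   + [(np.array([-1.0]), "release")] * 10)
        model = train(samples, seed=0)
        preds = [model.classes[np.argmax(forward(model, x))] for x, _ in samples]
        assert preds == [lab for _, lab in samples]

    def test_single_class_saturates(self):
        samples = [(np.array([0.3, -0.2]), "hold")] * 6
        model = train(samples, seed=0)
        for x, _ in samples:
            assert forward(model, x)[model.classes.index("hold")] >= 0.99

    def test_declared_class_without_samples_rejected(self):
        samples = [(np.array([0.3]), "hold")] * 4
        with pytest.raises(ValueError, match="zero samples"):
            train(samples, classes=("hold", "release"))

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        samples = [(rng.normal(size=4), "hold" if i % 2 else "release")
                   for i in range(20)]
        w1 = train(samples, seed=3).weights
        w2 = train(samples, seed=3).weights
        assert np.array_equal(w1, w2)

    def test_loglik_nondecreasing_with_small_lr(self):
        rng = np.random.default_rng(8)
        samples = [(rng.normal(size=2) + (2 if i % 2 else 0), "hold" if i % 2 else "release")
                   for i in range(30)]
        X = np.array([x for x, _ in samples])
        y = np.array([0 if lab == "hold" else 1 for _, lab in samples])

        def loglik(model):
            p = np.array([forward(model, x) for x in X])
            return float(np.log(p[np.arange(len(y)), y]).sum())

        lls = [loglik(train(samples, lr=0.01, epochs=n, seed=1))
               for n in (1, 10, 50, 200)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        samples = [(rng.normal(size=3), "hold" if i % 2 else "release")
                   for i in range(10)]
        model = train(samples, seed=1)
        model.to_json(tmp_path / "model.json")
        back = LlgmnModel.from_json(tmp_path / "model.json")
        assert np.array_equal(back.weights, model.weights)
        assert back.classes == model.classes


class TestClassifyMotion:
    def test_rest_recording_is_all_rest(self, cal, trained_model):
        sched = synth.SessionSchedule(duration=4.0, seed=0)
        rec = synth.gen_emg(sched, cal, seed=0)
        labels = classify_motion(rec, cal, trained_model)
        assert set(labels.labels) == {"rest"}

    def test_infinite_gate_is_all_rest(self, cal, trained_model):
        sched = synth.SessionSchedule(
            hold_windows=[(1.0, 3.0)], duration=5.0, seed=1)
        rec = synth.gen_emg(sched, cal, seed=1)
        labels = classify_motion(rec, cal, trained_model, mcl_gate=np.inf)
        assert set(labels.labels) == {"rest"}

    def test_hold_windows_recovered_with_high_jaccard(self, cal, trained_model):
        # 8 hold/release movements over ~30 s (2-s holds): with a causal 3 Hz
        # envelope the label boundaries lag by ~the filter delay, so the
        # Jaccard overlap is bounded near (W-L)/(W+L) and needs holds much
        # longer than the lag
        sched = synth.SessionSchedule.generate(n_discs=8, seed=9, mean_gap=4.0,
                                               hold_fraction=0.5)
        rec = synth.gen_emg(sched, cal, seed=9)
        labels = classify_motion(rec, cal, trained_model)
        t = rec.t
        truth = np.zeros(len(t), dtype=bool)
        for a, b in sched.hold_windows:
            truth |= (t >= a) & (t < b)
        pred = np.array([lab == "hold" for lab in labels.labels])
        jacc = (truth & pred).sum() / (truth | pred).sum()
        assert jacc >= 0.9


class TestTotalHoldTime:
    def test_known_segment_sum(self):
        dt = 0.005
        labels = (["hold"] * 200 + ["rest"] * 100) * 8
        assert total_hold_time(MotionLabelSeries(labels, dt)) == pytest.approx(8.0)

    def test_empty_series_is_zero(self):
        assert total_hold_time(MotionLabelSeries([], 0.005)) == 0.0

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(0)
        a = list(rng.choice(["hold", "release", "rest"], size=300))
        b = list(rng.choice(["hold", "release", "rest"], size=200))
        dt = 0.005
        assert total_hold_time(MotionLabelSeries(a + b, dt)) == pytest.approx(
            total_hold_time(MotionLabelSeries(a, dt))
            + total_hold_time(MotionLabelSeries(b, dt)))
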
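"""Context-adaptive network: branches, merge formulations, training."""

import numpy as np
import pytest

from flightcall.canet import (ClipBatch, ContextAdaptiveDetector,
                              classification_accuracy, train)
from flightcall.nn import sigmoid


@pytest.fixture(scope="module")
def inputs():
    rng = np.random.default_rng(42)
    clips = rng.normal(size=(16, 104, 128))
    ctx = rng.normal(size=(16, 9, 32))
    return clips, ctx


def fresh(formulation, seed=0, dtype=np.float64):
    return ContextAdaptiveDetector(formulation, seed=seed, dtype=dtype)


class TestBranches:
    def test_main_embedding_shape_and_nonnegativity(self, inputs):
        clips, _ = inputs
        z, _ = fresh("baseline").forward_main(clips)
        assert z.shape == (16, 64)
        assert np.all(z >= 0)

    def test_zero_clip_zero_embedding(self):
        z, _ = fresh("baseline").forward_main(np.zeros((1, 104, 128)))
        assert np.all(z == 0)

    def test_time_axis_downsampled_sixteenfold(self):
        # two 4x pools: 104 frames -> 25 -> 5 before the last conv; the
        # receptive-field stride along time is 16 frames (~24 ms)
        m = fresh("baseline")
        x = np.zeros((1, 104, 128, 1))
        h1, _ = __import__("flightcall.nn", fromlist=["nn"]).conv2d_forward(
            x, m.params["c1_W"], m.params["c1_b"])
        assert h1.shape[1:3] == (100, 124)

    def test_deterministic_given_seed(self, inputs):
        clips, _ = inputs
        z1, _ = fresh("baseline", seed=5).forward_main(clips)
        z2, _ = fresh("baseline", seed=5).forward_main(clips)
        assert np.array_equal(z1, z2)

    def test_wrong_clip_shape_rejected(self):
        with pytest.raises(ValueError):
            fresh("baseline").forward_main(np.zeros((1, 50, 128)))

    def test_aux_embedding_and_conv_activation_count(self, inputs):
        _, ctx = inputs
        m = fresh("at")
        z_aux, cache = m.forward_aux(ctx)
        assert z_aux.shape == (16, 64)
        assert np.all(z_aux >= 0)
        # conv stage: 8 kernels spanning all 32 bands x 9 quantile rows
        x, _, r1_shape, _, _ = cache
        assert r1_shape == (16, 9, 8)
        assert int(np.prod(r1_shape[1:])) == 72

    def test_aux_depends_only_on_slice(self, inputs):
        _, ctx = inputs
        m = fresh("at")
        z1, _ = m.forward_aux(ctx[:1])
        z2, _ = m.forward_aux(ctx[:1].copy())
        assert np.array_equal(z1, z2)

    def test_zero_slice_zero_embedding(self):
        z, _ = fresh("at").forward_aux(np.zeros((1, 9, 32)))
        assert np.all(z == 0)

    def test_wrong_slice_shape_rejected(self):
        with pytest.raises(ValueError):
            fresh("at").forward_aux(np.zeros((1, 5, 32)))


class TestMerge:
    @pytest.mark.parametrize("formulation", ["baseline", "aw", "at", "moe"])
    def test_zero_everything_gives_half(self, formulation):
        m = fresh(formulation)
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        y, _ = m.forward(np.zeros((1, 104, 128)), np.zeros((1, 9, 32)))
        assert y[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("formulation", ["baseline", "aw", "at", "moe"])
    def test_output_strictly_in_unit_interval(self, formulation, inputs):
        clips, ctx = inputs
        y, _ = fresh(formulation).forward(clips, ctx)
        assert np.all((y > 0) & (y < 1))

    def test_unknown_formulation_rejected(self):
        with pytest.raises(ValueError):
            ContextAdaptiveDetector("gated")

    def test_context_required_for_adaptive_models(self, inputs):
        clips, _ = inputs
        with pytest.raises(ValueError, match="context"):
            fresh("at").forward(clips, None)

    def test_moe_flat_gate_when_aux_weights_vanish(self, inputs):
        # zero adaptive weights and constant expert bias: the gate is the
        # flat histogram (1/K per expert)
        clips, ctx = inputs
        m = fresh("moe")
        m.params["w_aux_m"] = np.zeros_like(m.params["w_aux_m"])
        m.params["b_aux"] = np.full_like(m.params["b_aux"], 0.7)
        _, _, (_, _, gate, _) = m.merge(*_embed(m, clips, ctx))
        assert np.allclose(gate, 0.25)

    def test_moe_gates_sum_to_one(self, inputs):
        clips, ctx = inputs
        m = fresh("moe")
        _, _, (_, _, gate, _) = m.merge(*_embed(m, clips, ctx))
        assert np.allclose(gate.sum(axis=1), 1.0)


def _embed(model, clips, ctx):
    z, _ = model.forward_main(clips)
    z_aux, _ = model.forward_aux(ctx)
    return z, z_aux


@pytest.fixture(scope="module")
def draws():
    rng = np.random.default_rng(7)
    return np.abs(rng.normal(size=(1000, 64))), rng.normal(size=(1000, 9, 32))


@pytest.fixture(scope="module")
def baseline():
    return fresh("baseline", seed=3)


class TestBaselineReduction:
    """Each adaptive formulation contains the static baseline Eq-for-Eq."""

    def _baseline_out(self, baseline, z):
        return sigmoid(baseline.params["b"][0] + z @ baseline.params["w"])

    def test_aw_reduces_to_baseline(self, draws, baseline):
        # zero aux dense weights, biases set to the baseline's w (requires
        # w >= 0, which ReLU embeddings admit): z_aux is constant = w
        z, ctx = draws
        w = np.abs(baseline.params["w"])
        m = fresh("aw", seed=3)
        m.params["a2_W"] = np.zeros_like(m.params["a2_W"])
        m.params["a2_b"] = w.copy()
        m.params["b"] = baseline.params["b"].copy()
        z_aux, _ = m.forward_aux(ctx)
        y, _, _ = m.merge(z, z_aux)
        expect = sigmoid(baseline.params["b"][0] + z @ w)
        assert np.allclose(y, expect, atol=1e-6)

    def test_at_reduces_to_baseline(self, draws, baseline):
        # constant z_aux with w_aux . z_aux equal to the baseline bias b
        z, ctx = draws
        b = 0.37
        m = fresh("at", seed=3)
        m.params["w"] = baseline.params["w"].copy()
        m.params["a2_W"] = np.zeros_like(m.params["a2_W"])
        m.params["a2_b"] = np.full(64, 1.0)
        m.params["w_aux"] = np.full(64, b / 64.0)
        z_aux, _ = m.forward_aux(ctx)
        y, _, _ = m.merge(z, z_aux)
        expect = sigmoid(b + z @ baseline.params["w"])
        assert np.allclose(y, expect, atol=1e-6)

    def test_moe_reduces_to_baseline(self, draws, baseline):
        # vanishing adaptive weights and constant aux bias: flat gate, so
        # y = sigma(b + (1/K) sum_n w(n) z(n)); scaling w by K recovers the
        # baseline exactly
        z, ctx = draws
        m = fresh("moe", seed=3)
        m.params["w"] = 4.0 * baseline.params["w"].copy()
        m.params["b"] = baseline.params["b"].copy()
        m.params["w_aux_m"] = np.zeros_like(m.params["w_aux_m"])
        m.params["b_aux"] = np.zeros_like(m.params["b_aux"])
        z_aux, _ = m.forward_aux(ctx)
        y, _, _ = m.merge(z, z_aux)
        expect = self._baseline_out(baseline, z)
        assert np.allclose(y, expect, atol=1e-6)


class TestAdaptiveThresholdView:
    def test_zero_projection_returns_tau(self):
        m = fresh("at")
        m.params["w_aux"] = np.zeros(64)
        thr = m.adaptive_threshold_view(0.3, np.random.default_rng(0)
                                        .normal(size=(5, 9, 32)))
        assert np.allclose(thr, 0.3)

    def test_decision_equivalence_on_random_draws(self):
        # [y > tau] from the merge must agree with comparing the static
        # detection function against the time-varying threshold
        rng = np.random.default_rng(12)
        m = fresh("at", seed=12)
        tau = 0.4
        z = np.abs(rng.normal(size=(1000, 64)))
        ctx = rng.normal(size=(1000, 9, 32))
        z_aux, _ = m.forward_aux(ctx)
        y, _, _ = m.merge(z, z_aux)
        static = sigmoid(z @ m.params["w"])
        thr = m.adaptive_threshold_view(tau, ctx)
        assert np.array_equal(y > tau, static > thr)

    def test_threshold_monotone_decreasing_in_projection(self):
        m = fresh("at")
        ctx = np.abs(np.random.default_rng(1).normal(size=(50, 9, 32)))
        m.params["a2_W"] = np.abs(m.params["a2_W"])
        m.params["w_aux"] = np.abs(m.params["w_aux"])
        z_aux, _ = m.forward_aux(ctx)
        proj = z_aux @ m.params["w_aux"]
        thr = m.adaptive_threshold_view(0.5, ctx)
        order = np.argsort(proj)
        assert np.all(np.diff(thr[order]) <= 1e-12)

    def test_requires_at_formulation_and_valid_tau(self):
        with pytest.raises(ValueError):
            fresh("baseline").adaptive_threshold_view(0.5, np.zeros((1, 9, 32)))
        with pytest.raises(ValueError):
            fresh("at").adaptive_threshold_view(1.5, np.zeros((1, 9, 32)))


class TestGradients:
    @pytest.mark.parametrize("formulation", ["baseline", "aw", "at", "moe"])
    def test_finite_difference_agreement(self, formulation):
        # directional derivative on a 1-clip batch, float64
        rng = np.random.default_rng(3)
        m = fresh(formulation, seed=3)
        clips = rng.normal(size=(1, 104, 128))
        ctx = rng.normal(size=(1, 9, 32))
        labels = np.array([1.0])

        def loss():
            y, _ = m.forward(clips, ctx)
            return m.loss(y, labels)[0]

        y, caches = m.forward(clips, ctx)
        _, da = m.loss(y, labels)
        grads = m.backward(da, caches)
        for name, g in grads.items():
            v = np.random.default_rng(hash(name) % 2**31).normal(size=g.shape)
            eps = 1e-7
            p = m.params[name]
            p += eps * v
            lp = loss()
            p -= 2 * eps * v
            lm = loss()
            p += eps * v
            fd = (lp - lm) / (2 * eps)
            an = float((g * v).sum())
            assert an == pytest.approx(fd, rel=1e-4), name


class TestTraining:
    def _toy_batch(self, n=64, seed=0):
        # separable toy task: positives carry a bright block mid-clip
        rng = np.random.default_rng(seed)
        clips = rng.normal(0, 0.3, size=(n, 104, 128))
        labels = np.tile([0.0, 1.0], n // 2)
        clips[labels == 1, 40:60, 50:70] += 2.0
        ctx = rng.normal(size=(n, 9, 32))
        return ClipBatch(clips, labels, ctx)

    def test_capacity_overfits_toy_set(self):
        batch = self._toy_batch()
        m = ContextAdaptiveDetector("baseline", seed=1)
        hist = train(m, batch, epochs=20, seed=1)
        assert hist["train_acc"][-1] >= 0.95

    def test_same_seed_identical_histories(self):
        batch = self._toy_batch(n=32)
        h1 = train(ContextAdaptiveDetector("at", seed=2), batch,
                   epochs=3, seed=2)
        h2 = train(ContextAdaptiveDetector("at", seed=2), batch,
                   epochs=3, seed=2)
        assert h1["train_loss"] == h2["train_loss"]

    def test_sensor_overlap_between_splits_rejected(self):
        batch = self._toy_batch(n=8)
        batch.sensor_ids = ["s1"] * 8
        val = self._toy_batch(n=8, seed=1)
        val.sensor_ids = ["s1"] * 8
        with pytest.raises(ValueError, match="sensors"):
            train(ContextAdaptiveDetector("baseline"), batch, val, epochs=1)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train(ContextAdaptiveDetector("baseline"),
                  ClipBatch(np.zeros((0, 104, 128)), np.zeros(0)), epochs=1)

    def test_checkpoint_roundtrip(self, tmp_path, inputs):
        clips, ctx = inputs
        m = ContextAdaptiveDetector("moe", seed=9)
        m.feature_mean, m.feature_std = 0.2, 1.7
        path = tmp_path / "model.fcmodel"
        m.save(path)
        m2 = ContextAdaptiveDetector.load(path)
        y1, _ = m.forward(clips.astype(np.float32), ctx.astype(np.float32))
        y2, _ = m2.forward(clips.astype(np.float32), ctx.astype(np.float32))
        assert np.array_equal(y1, y2)
        assert m2.pcen_params == m.pcen_params


class TestClassificationAccuracy:
    def test_perfect_predictions(self):
        assert classification_accuracy([1.0, 0.0], [1.0, 0.0]) == 1.0

    def test_boundary_half_counts_as_wrong(self):
        assert classification_accuracy([0.5, 0.5], [1.0, 0.0]) == 0.0

    def test_hand_enumeration(self):
        acc = classification_accuracy([0.9, 0.2, 0.6], [1.0, 0.0, 0.0])
        assert acc == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy([0.5], [1.0, 0.0])
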
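"""TCN architecture, gradients, splitting and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmp_ee.preprocessing import WindowSet
from rmp_ee.tcn import (TcnConfig, TcnRegressor, TrainConfig, build_tcn,
                        cross_validate, predict_ee, receptive_field,
                        split_data, train)
from tests.conftest import make_windows


def influence_count(model: TcnRegressor, t_len: int, delta: float = 1e3) -> int:
    """Independent receptive-field oracle: count input positions whose
    perturbation changes the final-time-step output."""
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 1.0, (1, t_len, model.in_channels)).astype(np.float32)
    base = model.forward(x)[0]
    count = 0
    for i in range(t_len):
        xp = x.copy()
        xp[0, i, :] += delta
        if abs(model.forward(xp)[0] - base) > 1e-4:
            count += 1
    return count


class TestReceptiveField:
    @pytest.mark.parametrize("kernel,n,expected", [
        (1, 4, 1),   # kernel 1 sees only the current sample
        (3, 1, 3),
        (3, 5, 63),
        (2, 3, 8),
    ])
    def test_analytic_formula(self, kernel, n, expected):
        assert receptive_field(kernel, n) == expected

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ValueError):
            receptive_field(0, 3)
        with pytest.raises(ValueError):
            receptive_field(3, 0)

    @pytest.mark.parametrize("kernel,n_dil,blocks", [
        (3, 2, 1), (3, 3, 2), (2, 4, 2), (3, 5, 2),
    ])
    def test_matches_perturbation_oracle(self, kernel, n_dil, blocks):
        """The analytic RF equals the number of influential input positions
        of a randomly initialized network."""
        cfg = TcnConfig(filters=8, n_dilations=n_dil, kernel=kernel,
                        residual_blocks=blocks)
        model = TcnRegressor(cfg, in_channels=4, seed=3)
        rf = receptive_field(kernel, n_dil)
        assert influence_count(model, rf + 10) == rf


class TestArchitecture:
    def test_one_scalar_per_window(self):
        model = build_tcn(TcnConfig(filters=8), seed=0)
        x = np.random.default_rng(0).normal(0, 1, (7, 75, 4))
        assert model.forward(x).shape == (7,)

    def test_causality_future_samples_do_not_affect_past_outputs(self):
        model = build_tcn(TcnConfig(filters=8, n_dilations=3), seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (2, 40, 4)).astype(np.float32)
        full = model.predict_sequence(x)
        for t in (5, 20, 38):
            x_mod = x.copy()
            x_mod[:, t + 1:, :] = 0.0
            assert np.array_equal(model.predict_sequence(x_mod)[:, :t + 1],
                                  full[:, :t + 1])

    def test_zero_weights_predict_head_bias(self):
        model = build_tcn(TcnConfig(filters=8, n_dilations=2), seed=0)
        model.set_weights([np.zeros_like(p) for p in model.params()])
        model.head_b[0] = 1.5
        x = np.random.default_rng(1).normal(0, 1, (4, 30, 4))
        assert np.allclose(model.forward(x), 1.5)

    def test_gradients_match_finite_differences(self):
        cfg = TcnConfig(filters=5, n_dilations=3, kernel=2, residual_blocks=2)
        model = TcnRegressor(cfg, in_channels=3, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (3, 18, 3)).astype(np.float32)
        y = rng.normal(0, 1, 3).astype(np.float32)
        pred = model.forward(x, keep=True)
        model.zero_grad()
        model.backward((2.0 / 3) * (pred - y).astype(np.float32))
        analytic = [g.copy() for g in model.grads()]
        eps = 1e-3
        for p, g in zip(model.params(), analytic):
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = np.mean((model.forward(x) - y) ** 2)
                flat[i] = orig - eps
                lm = np.mean((model.forward(x) - y) ** 2)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(num, abs=2e-2, rel=2e-2)


class TestSplitData:
    @pytest.mark.parametrize("n,expected_valid", [(7950, 1590), (4875, 975)])
    def test_validation_counts_match_published_bookkeeping(self, n, expected_valid):
        ws = make_windows(n, n_samples=2)
        tr, va, te = split_data(ws, seed=0)
        assert len(va) == expected_valid
        assert len(tr) + len(te) == n - expected_valid  # the "80 %" column

    def test_exact_fractions(self):
        tr, va, te = split_data(make_windows(100, n_samples=2), seed=1)
        assert (len(tr), len(va), len(te)) == (55, 20, 25)

    def test_disjoint_cover(self):
        ws = make_windows(200, n_samples=2)
        parts = split_data(ws, seed=2)
        ids = [id(w) for p in parts for w in p]
        assert len(ids) == 200 == len(set(ids))

    def test_subject_mode_keeps_subjects_whole(self):
        ws = make_windows(120, n_samples=2, subjects=6)
        tr, va, te = split_data(ws, seed=3, mode="subject")
        seen = {}
        for name, part in (("tr", tr), ("va", va), ("te", te)):
            for sid in set(part.subject_ids()):
                assert seen.setdefault(sid, name) == name

    def test_subject_mode_needs_three_subjects(self):
        ws = make_windows(40, n_samples=2, subjects=2)
        with pytest.raises(ValueError, match="3 subjects"):
            split_data(ws, seed=0, mode="subject")

    @given(seed=st.integers(0, 100))
    @settings(max_examples=10, deadline=None)
    def test_deterministic_given_seed(self, seed):
        ws = make_windows(60, n_samples=2)
        a = split_data(ws, seed=seed)
        b = split_data(ws, seed=seed)
        for pa, pb in zip(a, b):
            assert [w.start for w in pa] == [w.start for w in pb]


def _quick_train(ws, epochs=15, seed=0, filters=8, n_dilations=3, lr=0.01):
    tr, va, te = split_data(ws, seed=seed)
    cfg = TrainConfig(lr=lr, epochs=epochs, batch=32, seed=seed)
    model = build_tcn(TcnConfig(filters=filters, n_dilations=n_dilations),
                      seed=seed)
    return train(model, tr, va, cfg), tr, va, te


class TestTraining:
    def test_constant_dataset_regresses_to_constant(self):
        """Degenerate regression: a repeated input with a constant target
        is fitted exactly."""
        sig = np.random.default_rng(5).normal(0, 1, (4, 8))
        const = WindowSet([type(w)(start=w.start, signal=sig, target_ee=3.0,
                                   target_vo2=9.0, subject_id=w.subject_id)
                           for w in make_windows(120, seed=5)])
        trained, tr, va, te = _quick_train(const, epochs=30)
        pred = predict_ee(trained, te)
        assert np.allclose(pred, 3.0, atol=1e-2)

    def test_loss_decreases_and_learns_signal(self):
        ws = make_windows(400, seed=6)
        trained, tr, va, te = _quick_train(ws, epochs=30)
        hist = trained.history["train_loss"]
        assert hist[-1] < hist[0]
        pred = predict_ee(trained, te)
        from rmp_ee.evaluation import r_squared
        assert r_squared(pred, te.targets("ee")) > 0.5

    def test_seed_reproducibility(self):
        ws = make_windows(150, seed=7)
        t1, *_ = _quick_train(ws, epochs=2, seed=11)
        t2, *_ = _quick_train(ws, epochs=2, seed=11)
        assert t1.history["train_loss"] == t2.history["train_loss"]

    def test_predictions_nonnegative_and_stateless(self):
        ws = make_windows(150, seed=8)
        trained, tr, va, te = _quick_train(ws, epochs=5)
        pred = predict_ee(trained, te)
        assert np.all(pred >= 0.0)
        rev = WindowSet(te.windows[::-1])
        assert np.allclose(predict_ee(trained, rev), pred[::-1])

    def test_window_shape_mismatch_rejected(self):
        ws = make_windows(150, seed=9)
        trained, *_ = _quick_train(ws, epochs=1)
        bad = make_windows(5, n_samples=16)
        with pytest.raises(ValueError, match="shape|channel|length"):
            predict_ee(trained, bad)

    def test_cross_validation_reports_every_fold(self):
        ws = make_windows(120, seed=10)
        cfg = TrainConfig(epochs=2, batch=64, folds=3, seed=0)
        scores = cross_validate(TcnConfig(filters=6, n_dilations=2), cfg, ws)
        assert [s["fold"] for s in scores] == [0, 1, 2]
        assert sum(s["n"] for s in scores) == 120

    def test_model_round_trip(self, tmp_path):
        ws = make_windows(120, seed=12)
        trained, tr, va, te = _quick_train(ws, epochs=2)
        trained.save(tmp_path / "m")
        from rmp_ee.tcn import TrainedModel
        loaded = TrainedModel.load(tmp_path / "m")
        assert np.allclose(predict_ee(loaded, te), predict_ee(trained, te))
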
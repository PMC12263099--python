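"""Windowing, normalization, training mechanics and overlap-averaged inference."""

import numpy as np
import pytest

import catrans
from catrans import CalciumTraceSet, FrameLabels
from catrans import ml_detection as ml


def zero_traceset(n_cells, n_frames, c_value=0.0):
    C = np.full((n_cells, n_frames), c_value)
    ts = CalciumTraceSet(
        list(range(n_cells)), C=C, S=np.zeros((n_cells, n_frames)),
        dff=np.zeros((n_cells, n_frames)),
    )
    return ts


class TestNormalizeCell:
    def test_scales_to_unit_max(self, small_noisy_ts):
        ts, _, _ = small_noisy_ts
        c_norm, d_norm, consts = ml.normalize_cell(ts, 0)
        assert c_norm.max() == pytest.approx(1.0)
        assert d_norm.max() == pytest.approx(1.0)
        # de-normalization through the stored constants reproduces the input
        # to machine precision
        assert np.allclose(c_norm * consts["C"], ts.C[0], rtol=1e-14, atol=0)

    def test_all_zero_channel_warns_and_passes_through(self):
        ts = zero_traceset(1, 100)
        with pytest.warns(RuntimeWarning, match="no positive"):
            c_norm, d_norm, consts = ml.normalize_cell(ts, 0)
        assert consts["C"] == 1.0
        assert np.array_equal(c_norm, ts.C[0])


class TestMakeWindows:
    def test_window_count_arithmetic(self):
        # 27,000 frames / step 200 with 200-frame cores -> 135 per cell
        ts = zero_traceset(1, 27_000)
        labels = FrameLabels(np.zeros((1, 27_000), dtype=np.int8))
        cfg = ml.TrainConfig(seq_len=200, slack=50)
        with pytest.warns(RuntimeWarning):
            windows = ml.make_windows(ts, labels, cfg, step=200, stratify=False)
        assert len(windows) == 135
        assert all(w.inputs.shape == (300, 2) for w in windows)

    def test_stratification_keeps_exactly_the_informative_windows(self):
        ts = zero_traceset(1, 1000)
        ts.C[0, 50:80] = 1.0  # positive C only in the first core
        mask = np.zeros((1, 1000), dtype=np.int8)
        mask[0, 60:70] = 1
        cfg = ml.TrainConfig(seq_len=200, slack=50)
        windows = ml.make_windows(ts, FrameLabels(mask), cfg, step=200)
        assert [w.t0 for w in windows] == [0]

    def test_stratification_matches_bruteforce_filter(self, small_noisy_ts):
        ts, labels, _ = small_noisy_ts
        cfg = ml.TrainConfig(seq_len=200, slack=50)
        step = 100
        kept = {
            (w.cell_id, w.t0)
            for w in ml.make_windows(ts, labels, cfg, step=step)
        }
        expected = set()
        for row, cid in enumerate(ts.cell_ids):
            for t0 in range(0, ts.n_frames - 200 + 1, step):
                core_lab = labels.mask[row, t0 : t0 + 200]
                core_c = ts.C[row, t0 : t0 + 200]
                if core_lab.any() or (core_c > 0).any():
                    expected.add((cid, t0))
        assert kept == expected

    def test_stratification_never_drops_ground_truth_positives(
        self, small_noisy_ts
    ):
        ts, labels, _ = small_noisy_ts
        cfg = ml.TrainConfig(seq_len=200, slack=50)
        windows = ml.make_windows(ts, labels, cfg, step=200)
        covered = sum(int(w.targets.sum()) for w in windows)
        assert covered == int(labels.mask.sum())

    def test_edge_windows_are_zero_padded(self, small_noisy_ts):
        ts, labels, _ = small_noisy_ts
        cfg = ml.TrainConfig(seq_len=200, slack=50)
        first = ml.make_windows(ts, labels, cfg, step=100, stratify=False)[0]
        assert first.t0 == 0
        assert np.array_equal(first.inputs[:50], np.zeros((50, 2)))

    def test_too_long_core_is_fatal(self):
        ts = zero_traceset(1, 100)
        labels = FrameLabels(np.zeros((1, 100), dtype=np.int8))
        with pytest.raises(ValueError, match="seq_len"):
            ml.make_windows(ts, labels, ml.TrainConfig(seq_len=200))


class TestBuildModel:
    @pytest.mark.parametrize(
        "kind,hidden,heads",
        [
            ("gru", 30, 1),
            ("lstm", 30, 1),
            ("transformer", 42, 2),
            ("local_transformer", 32, 1),
        ],
    )
    def test_reference_defaults_resolved_per_kind(self, kind, hidden, heads):
        cfg = ml.TrainConfig(model_kind=kind)
        assert cfg.hidden_size == hidden
        assert cfg.heads == heads
        assert cfg.n_layers == 3
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.seq_len == 200 and cfg.slack == 50

    def test_unknown_kind_is_fatal(self):
        with pytest.raises(ValueError, match="model_kind"):
            ml.TrainConfig(model_kind="mlp")

    def test_forward_contract_on_zero_window(self):
        cfg = ml.TrainConfig(model_kind="gru", seq_len=40, slack=10)
        model = ml.build_model(cfg)
        logits = model.forward_logits(np.zeros((2, cfg.context_len, 2)))
        assert logits.shape == (2, 40)
        assert np.isfinite(logits).all()


class TestTrain:
    def _tiny_setup(self, seed=0):
        cfg = catrans.GeneratorConfig(n_cells=3, n_frames=1200, seed=13)
        ts, labels, _ = catrans.generate_traceset(cfg)
        tc = ml.TrainConfig(model_kind="gru", seq_len=100, slack=20,
                            epochs=1, patience=0, seed=seed)
        tw = ml.make_windows(ts, labels, tc, cell_ids=[0, 1])
        vw = ml.make_windows(ts, labels, tc, cell_ids=[2])
        return tc, tw, vw

    def test_single_epoch_history(self):
        tc, tw, vw = self._tiny_setup()
        model, history = ml.train(ml.build_model(tc), tw, vw)
        assert len(history) == 1
        assert {"epoch", "train_loss", "val_loss", "val_macro_f1"} <= set(
            history[0]
        )

    def test_same_seed_is_bit_reproducible(self):
        tc, tw, vw = self._tiny_setup(seed=5)
        m1, h1 = ml.train(ml.build_model(tc), tw, vw)
        m2, h2 = ml.train(ml.build_model(tc), tw, vw)
        assert h1 == h2
        assert all(
            np.array_equal(a, b)
            for a, b in zip(m1.net.state_dict(), m2.net.state_dict())
        )

    def test_empty_train_set_is_fatal(self):
        tc, tw, vw = self._tiny_setup()
        with pytest.raises(ValueError, match="empty"):
            ml.train(ml.build_model(tc), [], vw)

    def test_overlapping_train_val_cells_is_fatal(self):
        tc, tw, vw = self._tiny_setup()
        with pytest.raises(ValueError, match="overlap"):
            ml.train(ml.build_model(tc), tw, tw)

    def test_checkpoint_round_trip(self, tmp_path):
        tc, tw, vw = self._tiny_setup()
        model, _ = ml.train(ml.build_model(tc), tw, vw)
        model.norm_constants = {0: {"C": 2.0, "dff": 1.5}}
        ml.save_model(model, tmp_path / "model.npz")
        back = ml.load_model(tmp_path / "model.npz")
        assert back.cfg == model.cfg
        assert back.norm_constants == {"0": {"C": 2.0, "dff": 1.5}}
        x = np.random.default_rng(0).normal(size=(1, tc.context_len, 2))
        assert np.array_equal(back.forward_logits(x), model.forward_logits(x))


class ConstantLogitModel:
    """Stand-in detector emitting a constant logit; synthetic test double."""

    def __init__(self, cfg, value=0.0):
        self.cfg = cfg
        self.value = value

    def forward_logits(self, inputs):
        return np.full((inputs.shape[0], self.cfg.seq_len), self.value)


class TestPredictFrames:
    def test_constant_zero_logit_gives_half_probability(self):
        ts = zero_traceset(1, 500, c_value=1.0)
        cfg = ml.TrainConfig(seq_len=100, slack=10)
        model = ConstantLogitModel(cfg, 0.0)
        probs = ml.predict_frames(model, ts, step=40)
        assert probs.shape == (1, 500)
        assert np.allclose(probs, 0.5)

    def test_no_overlap_equals_concatenated_windows(self):
        cfg = catrans.GeneratorConfig(n_cells=1, n_frames=800, seed=3)
        ts, labels, _ = catrans.generate_traceset(cfg)
        tc = ml.TrainConfig(model_kind="gru", seq_len=100, slack=20, seed=1)
        model = ml.build_model(tc)
        probs = ml.predict_frames(model, ts, step=100)
        c_norm, d_norm, _ = ml.normalize_cell(ts, 0)
        channels = np.stack([c_norm, d_norm], axis=1)
        from catrans.ml_detection import _padded_context

        for t0 in range(0, 800, 100):
            x = _padded_context(channels, t0, tc)[None]
            logits = model.forward_logits(x)[0]
            assert np.allclose(
                probs[0, t0 : t0 + 100], 1 / (1 + np.exp(-logits)), atol=1e-6
            )

    def test_half_overlap_matches_bruteforce_accumulation(self):
        cfg = catrans.GeneratorConfig(n_cells=1, n_frames=600, seed=4)
        ts, _, _ = catrans.generate_traceset(cfg)
        tc = ml.TrainConfig(model_kind="gru", seq_len=200, slack=20, seed=2)
        model = ml.build_model(tc)
        probs = ml.predict_frames(model, ts, step=100)
        c_norm, d_norm, _ = ml.normalize_cell(ts, 0)
        channels = np.stack([c_norm, d_norm], axis=1)
        from catrans.ml_detection import _padded_context

        acc, cov = np.zeros(600), np.zeros(600)
        for t0 in (0, 100, 200, 300, 400):
            x = _padded_context(channels, t0, tc)[None]
            p = 1 / (1 + np.exp(-model.forward_logits(x)[0]))
            acc[t0 : t0 + 200] += p
            cov[t0 : t0 + 200] += 1
        assert cov.min() >= 1 and cov.max() == 2
        assert np.allclose(probs[0], acc / cov, atol=1e-6)


class TestClassify:
    def test_zero_probabilities_give_no_events(self):
        labels, events = ml.classify(np.zeros((2, 100)))
        assert labels.mask.sum() == 0 and events == []

    def test_probability_block_becomes_one_event(self):
        p = np.zeros((1, 100))
        p[0, 40:61] = 0.9
        _, events = ml.classify(p, threshold=0.5, min_run=2)
        assert [(e.rise_start, e.rise_stop) for e in events] == [(40, 60)]

    def test_event_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(9)
        # smooth noise so runs of every length occur
        p = np.convolve(rng.uniform(size=1000), np.ones(5) / 5, mode="same")
        p = np.clip(p, 0, 1)[None]
        counts = [
            len(ml.classify(p, threshold=t, min_run=2)[1])
            for t in (0.35, 0.5, 0.65, 0.8, 0.95)
        ]
        total = [
            ml.classify(p, threshold=t, min_run=1)[0].mask.sum()
            for t in (0.35, 0.5, 0.65, 0.8, 0.95)
        ]
        # positive-frame mass is monotone; event counts follow at min_run=1
        assert total == sorted(total, reverse=True)
        assert counts[0] >= counts[-1]

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ml.classify(np.array([[0.2, 1.4]]))
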
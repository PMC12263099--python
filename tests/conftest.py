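"""Shared fixtures: small synthetic corpora and (expensive) trained models.

The trained-model fixtures are session-scoped so the detector-quality and
architecture-comparison tests share one training run per architecture.
"""

import pytest
from hypothesis import HealthCheck, settings

import catrans
from catrans import ml_detection as ml
from catrans.evaluation import split_cells

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def small_noisy_ts():
    """3 noisy cells, 2000 frames: enough events to exercise detection."""
    cfg = catrans.GeneratorConfig(n_cells=3, n_frames=2000, seed=11)
    return catrans.generate_traceset(cfg)


@pytest.fixture
def noiseless_ts():
    cfg = catrans.GeneratorConfig(
        n_cells=2, n_frames=3000, noise_sigma=0.0, seed=7
    )
    return catrans.generate_traceset(cfg)


# ---------------------------------------------------------------------------
# ML corpus and trained models (expensive; session scoped, built on demand)
# ---------------------------------------------------------------------------

#: Study conditions for the detector-quality experiments: 10 cells of 5,000
#: frames at generator defaults, split 8/1/1.
ML_CORPUS_CFG = catrans.GeneratorConfig(n_cells=10, n_frames=5_000, seed=21)


@pytest.fixture(scope="session")
def ml_corpus():
    ts, labels, events = catrans.generate_traceset(ML_CORPUS_CFG)
    train_ids, val_ids, test_ids = split_cells(ts.cell_ids, seed=3)
    return {
        "ts": ts,
        "labels": labels,
        "events": events,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "test_ids": test_ids,
    }


def _fit(corpus, kind: str, epochs: int, patience: int, seed: int = 0):
    cfg = ml.TrainConfig(
        model_kind=kind, epochs=epochs, patience=patience, seed=seed
    )
    model = ml.build_model(cfg)
    tw = ml.make_windows(corpus["ts"], corpus["labels"], cfg,
                         cell_ids=corpus["train_ids"])
    vw = ml.make_windows(corpus["ts"], corpus["labels"], cfg,
                         cell_ids=corpus["val_ids"])
    model, history = ml.train(model, tw, vw)
    return model, history


@pytest.fixture(scope="session")
def gru_model(ml_corpus):
    """Reference GRU fit: early stopping on validation macro-F1, <=30 epochs."""
    model, history = _fit(ml_corpus, "gru", epochs=30, patience=5)
    return {"model": model, "history": history}


@pytest.fixture(scope="session")
def comparison_models(ml_corpus):
    """GRU / LSTM / standard transformer under one equal training budget."""
    out = {}
    for kind in ("gru", "lstm", "transformer"):
        model, history = _fit(ml_corpus, kind, epochs=8, patience=0)
        out[kind] = {"model": model, "history": history}
    return out


def heldout_report(corpus, model):
    """Frame-level metrics of a model on the corpus' held-out test cells."""
    probs = ml.predict_frames(model, corpus["ts"], cell_ids=corpus["test_ids"])
    pred, _ = ml.classify(probs, model.cfg.threshold, model.cfg.min_run)
    idx = [corpus["ts"].cell_index(c) for c in corpus["test_ids"]]
    return catrans.metrics_report(pred.mask, corpus["labels"].mask[idx])
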
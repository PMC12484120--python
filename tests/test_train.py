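"""Training loop, evaluation, and experiment grids at smoke scale."""

import numpy as np
import pytest

from mafnet import (ConfigurationError, ModelConfig, TrainConfig, build_model,
                    dice_loss, evaluate_model, load_checkpoint, run_ablation_grid,
                    train)
from mafnet.training import (TABLE2_COMBOS, TABLE5_DILATIONS, TABLE6_PATH_MODES,
                             TABLE7_OPTIMIZERS, _forward_eval, grid_configs)

SMALL = ModelConfig(stage_widths=(4, 8, 16, 32))
SMOKE = TrainConfig(epochs=2, batch_size=8, seed=0)


def test_train_config_defaults_match_study_settings():
    cfg = TrainConfig()
    assert (cfg.optimizer, cfg.learning_rate, cfg.epochs, cfg.batch_size) == \
        ("adam", 0.001, 200, 16)


def test_train_config_validation():
    with pytest.raises(ConfigurationError):
        TrainConfig(optimizer="lbfgs")
    with pytest.raises(ConfigurationError):
        TrainConfig(learning_rate=0.0)


def test_same_seed_gives_identical_loss_sequence(tiny_dataset):
    curves = []
    for _ in range(2):
        model = build_model(SMALL, seed=9)
        _, c = train(model, tiny_dataset, TrainConfig(epochs=5, batch_size=8, seed=9))
        curves.append(c)
    assert curves[0]["train_loss"].tolist() == curves[1]["train_loss"].tolist()
    assert curves[0]["val_loss"].tolist() == curves[1]["val_loss"].tolist()


@pytest.mark.parametrize("label,m,d,s", TABLE2_COMBOS)
def test_every_ablation_config_trains_with_finite_loss(tiny_dataset, label, m, d, s):
    cfg = ModelConfig(stage_widths=(4, 8, 16, 32), use_mafm=m, use_daem=d, use_dseem=s)
    model = build_model(cfg, seed=0)
    _, curves = train(model, tiny_dataset,
                      TrainConfig(epochs=3, batch_size=8, seed=0))
    assert len(curves) == 3
    assert np.isfinite(curves[["train_loss", "val_loss"]].to_numpy()).all()


def test_curves_row_count_and_columns(tiny_dataset):
    model = build_model(SMALL, seed=1)
    _, curves = train(model, tiny_dataset, TrainConfig(epochs=4, batch_size=8, seed=1))
    assert list(curves.columns) == ["epoch", "train_loss", "val_loss",
                                    "train_accuracy", "val_accuracy"]
    assert len(curves) == 4


def test_best_checkpoint_reload_reproduces_best_val_loss(tiny_dataset, tmp_path):
    model = build_model(SMALL, seed=2)
    _, curves = train(model, tiny_dataset,
                      TrainConfig(epochs=4, batch_size=8, seed=2),
                      checkpoint_path=tmp_path / "ckpt.npz",
                      curves_path=tmp_path / "curves.csv")
    reloaded = load_checkpoint(tmp_path / "ckpt.npz")
    preds = _forward_eval(reloaded, tiny_dataset.images("val"))
    val_loss = dice_loss(preds, tiny_dataset.masks("val"))
    assert abs(val_loss - curves["val_loss"].min()) <= 1e-6
    assert (tmp_path / "curves.csv").exists()


def test_nan_parameters_abort_with_diagnostic(tiny_dataset):
    model = build_model(SMALL, seed=0)
    next(model.parameters()).data[:] = np.nan
    with pytest.raises(RuntimeError, match="epoch 0"):
        train(model, tiny_dataset, TrainConfig(epochs=1, batch_size=8, seed=0))


class _StubModel:
    """Predicts a fixed probability map regardless of input."""

    def __init__(self, prob):
        self.prob = prob

    def predict(self, x):
        return np.broadcast_to(self.prob, x.shape[:1] + self.prob.shape).copy()


def test_evaluate_model_perfect_and_empty_predictions(tiny_dataset):
    masks = tiny_dataset.masks("val")
    perfect = _StubModel(np.clip(masks[0] * 0.98 + 0.01, 0.01, 0.99))
    rep = evaluate_model(perfect, tiny_dataset, split="val")
    for name in ("dice", "mcc", "jaccard", "accuracy", "recall"):
        assert rep.aggregate[name] == pytest.approx(1.0), name
    empty = _StubModel(np.full_like(masks[0], 0.01))
    rep0 = evaluate_model(empty, tiny_dataset, split="val")
    assert rep0.aggregate["recall"] == pytest.approx(0.0)


def test_evaluate_model_matches_metric_oracle(tiny_dataset):
    from mafnet import evaluate
    model = build_model(SMALL, seed=4)
    rep = evaluate_model(model, tiny_dataset, split="test")
    preds = _forward_eval(model, tiny_dataset.images("test"))
    again = evaluate(preds, tiny_dataset.masks("test"),
                     ids=tiny_dataset.ids("test"))
    assert rep.aggregate == again.aggregate


# -- grids ------------------------------------------------------------------


def test_grid_enumerations():
    rows2 = list(grid_configs("table2", SMALL, SMOKE))
    assert len(rows2) == 5
    rows5 = list(grid_configs("table5", SMALL, SMOKE))
    assert len(rows5) == 21
    assert rows5[0][1].mafm_dilations == (1, 2, 3)
    assert rows5[-1][1].mafm_dilations == (1, 7, 8)
    assert len(list(grid_configs("table6", SMALL, SMOKE))) == 3
    labels7 = [r[0] for r in grid_configs("table7", SMALL, SMOKE)]
    assert labels7 == list(TABLE7_OPTIMIZERS)
    with pytest.raises(ConfigurationError):
        list(grid_configs("table9", SMALL, SMOKE))


def test_table6_grid_trains_and_reports_all_metrics(tiny_dataset, tmp_path):
    df = run_ablation_grid(SMALL, TrainConfig(epochs=1, batch_size=8, seed=0),
                           "table6", tiny_dataset, out_csv=tmp_path / "t6.csv")
    assert df["config"].tolist() == list(TABLE6_PATH_MODES)
    assert {"dice", "mcc", "jaccard", "accuracy", "recall"} <= set(df.columns)
    assert np.isfinite(df[["dice", "mcc", "jaccard", "accuracy", "recall"]]
                       .to_numpy()).all()
    assert (tmp_path / "t6.csv").exists()
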
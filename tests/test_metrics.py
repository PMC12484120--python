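"""Dice loss and the five-metric suite against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mafnet import (ConfusionCounts, ContractError, confusion_counts, dice_loss,
                    evaluate, metrics_from_counts)
from mafnet.nn.tensor import Tensor

from conftest import naive_confusion


# -- Dice loss --------------------------------------------------------------


def test_dice_loss_perfect_overlap_is_zero(rng):
    y = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float64)
    assert dice_loss(y, y) <= 1e-6


def test_dice_loss_disjoint_is_one(rng):
    y = np.zeros((1, 1, 8, 8))
    y[0, 0, 2:5, 2:5] = 1.0
    assert dice_loss(np.zeros_like(y), y) >= 1.0 - 1e-6


def test_dice_loss_half_probability_example():
    assert abs(dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) - 0.5) <= 1e-9


def test_dice_loss_extent_mismatch():
    with pytest.raises(ContractError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 2)))


def test_dice_loss_differentiable_and_matches_finite_difference(rng):
    p = Tensor(rng.random((1, 1, 6, 6)) * 0.8 + 0.1, requires_grad=True)
    y = (rng.random((1, 1, 6, 6)) > 0.6).astype(np.float64)
    loss = dice_loss(p, y)
    loss.backward()
    eps = 1e-7
    i = (0, 0, 3, 3)
    pd = p.data.copy()
    pd[i] += eps
    num = (dice_loss(pd, y) - dice_loss(p.data, y)) / eps
    assert abs(num - p.grad[i]) < 1e-5


# -- confusion counts -------------------------------------------------------


def test_confusion_counts_trivial_cases():
    ones = np.ones((2, 2), dtype=np.uint8)
    zeros = np.zeros((2, 2), dtype=np.uint8)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.tn, c.fp, c.fn) == (4, 0, 0, 0)
    c = confusion_counts(ones, zeros)
    assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 4, 0)


def test_confusion_counts_match_nested_loop_oracle(rng):
    pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    c = confusion_counts(pred, truth)
    assert (c.tp, c.tn, c.fp, c.fn) == naive_confusion(pred, truth)
    assert c.total == 256


def test_confusion_counts_reject_non_binary():
    with pytest.raises(ContractError):
        confusion_counts(np.array([[0, 2]]), np.array([[0, 1]]))


# -- metrics from counts ----------------------------------------------------


def test_metrics_direct_substitution():
    m = metrics_from_counts(ConfusionCounts(tp=3, tn=11, fp=1, fn=1))
    assert m["dice"] == pytest.approx(0.75)
    assert m["jaccard"] == pytest.approx(0.6)
    assert m["recall"] == pytest.approx(0.75)
    assert m["accuracy"] == pytest.approx(0.875)


def test_mcc_perfect_prediction():
    assert metrics_from_counts(ConfusionCounts(5, 5, 0, 0))["mcc"] == pytest.approx(1.0)


def test_mcc_substitution_example():
    m = metrics_from_counts(ConfusionCounts(tp=2, tn=3, fp=1, fn=1))
    assert m["mcc"] == pytest.approx(5.0 / 12.0, abs=1e-12)


def test_degenerate_conventions():
    empty_both = metrics_from_counts(ConfusionCounts(0, 9, 0, 0))
    assert empty_both["dice"] == empty_both["jaccard"] == empty_both["recall"] == 1.0
    assert empty_both["mcc"] == 0.0
    assert empty_both["accuracy"] == 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tp=st.integers(0, 10_000), tn=st.integers(0, 10_000),
       fp=st.integers(0, 10_000), fn=st.integers(0, 10_000))
def test_jaccard_dice_algebraic_identity(tp, tn, fp, fn):
    if tp + tn + fp + fn == 0:
        return
    m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    assert abs(m["jaccard"] - m["dice"] / (2.0 - m["dice"])) <= 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 100_000))
def test_mcc_equals_pearson_correlation(seed):
    r = np.random.default_rng(seed)
    pred = (r.random(64) > r.random()).astype(np.uint8)
    truth = (r.random(64) > r.random()).astype(np.uint8)
    if len(np.unique(pred)) < 2 or len(np.unique(truth)) < 2:
        return
    m = metrics_from_counts(confusion_counts(pred, truth))
    pearson = np.corrcoef(pred.astype(float), truth.astype(float))[0, 1]
    assert abs(m["mcc"] - pearson) <= 1e-10


# -- evaluate ---------------------------------------------------------------


def test_evaluate_single_confident_image():
    pred = np.full((1, 1, 4, 4), 0.9)
    mask = np.ones((1, 1, 4, 4))
    rep = evaluate(pred, mask, threshold=0.5)
    assert rep.aggregate["dice"] == 1.0
    assert rep.n_images == 1


def _two_image_batch():
    masks = np.zeros((2, 1, 4, 4))
    masks[:, 0, :2, :2] = 1.0
    preds = np.zeros((2, 1, 4, 4))
    preds[0, 0, :2, :2] = 0.9            # dice 1.0
    preds[1, 0, 0, :2] = 0.9             # half the mask -> dice 2*2/(2+4)
    return preds, masks


def test_per_image_mean_aggregation():
    preds, masks = _two_image_batch()
    rep = evaluate(preds, masks, aggregation="per_image_mean")
    d1 = rep.per_image["dice"].tolist()
    assert d1[0] == pytest.approx(1.0)
    assert rep.aggregate["dice"] == pytest.approx(np.mean(d1))


def test_global_pool_equals_pooled_counts_and_differs_from_mean():
    preds, masks = _two_image_batch()
    pooled = evaluate(preds, masks, aggregation="global_pool")
    # oracle: recompute from summed per-image counts
    total = ConfusionCounts(0, 0, 0, 0)
    for i in range(2):
        total = total + confusion_counts((preds[i] >= 0.5).astype(np.uint8),
                                         masks[i].astype(np.uint8))
    assert pooled.aggregate == metrics_from_counts(total)
    mean = evaluate(preds, masks, aggregation="per_image_mean")
    assert pooled.aggregate["dice"] != pytest.approx(mean.aggregate["dice"])


def test_evaluate_validation():
    with pytest.raises(ContractError):
        evaluate(np.zeros((0, 1, 4, 4)), np.zeros((0, 1, 4, 4)))
    with pytest.raises(ContractError):
        evaluate(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)), threshold=1.5)
    with pytest.raises(ContractError):
        evaluate(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)), aggregation="median")


def test_report_serialization(tmp_path):
    preds, masks = _two_image_batch()
    rep = evaluate(preds, masks)
    rep.to_csv(tmp_path / "report.csv")
    rep.to_json(tmp_path / "report.json")
    import json

    import pandas as pd
    df = pd.read_csv(tmp_path / "report.csv")
    assert len(df) == 3  # two images + aggregate row
    payload = json.loads((tmp_path / "report.json").read_text())
    assert payload["n_images"] == 2
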
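"""Confusion counts, agreement criteria, ROC sweep and MAA."""

import numpy as np
import pytest

from retveins.evaluation import (
    ConfusionCounts,
    SweepResult,
    anchored_auc,
    confusion,
    criteria,
    maa,
    roc_sweep,
)
from retveins.refine import build_line_bank


def _constructed_masks():
    """10×10 frame: 20 gold px, prediction hits 15 of them plus 5 false alarms."""
    gold = np.zeros((10, 10), dtype=bool)
    gold[0:2, :] = True  # 20 vessel pixels
    pred = np.zeros((10, 10), dtype=bool)
    pred[0, :] = True
    pred[1, :5] = True  # 15 true positives
    pred[5, :5] = True  # 5 false alarms
    return pred, gold


class TestConfusion:
    def test_perfect_prediction(self, rng):
        gold = rng.random((12, 12)) < 0.3
        c = confusion(gold, gold)
        assert c.fp == c.fn == 0
        assert c.tp == gold.sum()

    def test_complement_prediction(self, rng):
        gold = rng.random((12, 12)) < 0.3
        c = confusion(~gold, gold)
        assert c.tp == c.tn == 0

    def test_constructed_example_counts(self):
        pred, gold = _constructed_masks()
        c = confusion(pred, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (15, 5, 5, 75)

    def test_fov_restriction(self):
        pred, gold = _constructed_masks()
        fov = np.zeros((10, 10), dtype=bool)
        fov[:5] = True  # excludes the false-alarm row
        c = confusion(pred, gold, fov)
        assert c.n_fov == 50
        assert c.fp == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestCriteria:
    def test_perfect_prediction_all_ones(self):
        r = criteria(ConfusionCounts(tp=30, fp=0, tn=70, fn=0))
        assert (r.sen, r.spe, r.ppv, r.npv, r.acc, r.kappa) == (1, 1, 1, 1, 1, 1)

    def test_worked_kappa_example(self):
        # P(E) = (20·20 + 80·80)/100² = 0.68; kappa = (0.9−0.68)/0.32
        r = criteria(ConfusionCounts(tp=15, fp=5, tn=75, fn=5))
        assert np.isclose(r.acc, 0.9)
        assert np.isclose(r.kappa, 0.6875)

    def test_all_negative_prediction(self):
        r = criteria(ConfusionCounts(tp=0, fp=0, tn=80, fn=20))
        assert r.sen == 0.0
        assert r.spe == 1.0

    def test_zero_denominator_reports_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = criteria(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert np.isnan(r.ppv)

    def test_matches_rederivation_from_raw_masks(self, rng):
        for _ in range(5):
            pred = rng.random((15, 15)) < 0.3
            gold = rng.random((15, 15)) < 0.3
            fov = rng.random((15, 15)) < 0.8
            r = criteria(confusion(pred, gold, fov))
            p, g = pred[fov], gold[fov]
            assert np.isclose(r.sen, (p & g).sum() / max(g.sum(), 1))
            assert np.isclose(r.acc, (p == g).mean())
            assert np.isclose(r.spe, (~p & ~g).sum() / max((~g).sum(), 1))


class TestAnchoredAuc:
    def test_single_midpoint_gives_half(self):
        pts, auc = anchored_auc(np.array([0.5]), np.array([0.5]))
        assert np.isclose(auc, 0.5)
        assert np.array_equal(pts[[0, -1]], [[0, 0], [1, 1]])

    def test_hand_trapezoid_example(self):
        _, auc = anchored_auc(np.array([0.2]), np.array([0.8]))
        # (0,0)-(0.2,0.8)-(1,1): 0.5·0.2·0.8 + 0.8·(0.8+1)/2 = 0.08 + 0.72
        assert np.isclose(auc, 0.80)

    def test_reversed_curve_complement(self, rng):
        fpf = np.sort(rng.uniform(0, 1, 7))
        tpf = np.sort(rng.uniform(0, 1, 7))
        _, auc = anchored_auc(fpf, tpf)
        _, auc_rev = anchored_auc(tpf, fpf)
        assert np.isclose(auc + auc_rev, 1.0)
        assert 0.0 <= auc <= 1.0


class TestRocSweep:
    def test_phantom_sweep_monotone_before_postprocess(self):
        from retveins.phantom import PhantomSpec, generate
        from retveins.pipeline import PipelineConfig, segment_stages

        p = generate(PhantomSpec(height=192, width=192, seed=11))
        stages = segment_stages(p.image, PipelineConfig(icgf_sigma=12.0))
        etas = np.arange(0.5, 5.0, 0.5)
        sweep = roc_sweep(
            stages["cleaned"], p.gold, p.fov, etas, apply_postprocess=False
        )
        # elongation shrinks with η, so both fractions are nonincreasing
        assert np.all(np.diff(sweep.tpf) <= 1e-12)
        assert np.all(np.diff(sweep.fpf) <= 1e-12)
        assert 0.0 <= sweep.auc <= 1.0

    def test_invalid_grid_rejected(self):
        mask = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError):
            roc_sweep(mask, mask, None, np.array([]))
        with pytest.raises(ValueError):
            roc_sweep(mask, mask, None, np.array([-1.0]))


def _fake_sweep(etas, acc):
    etas = np.asarray(etas, float)
    acc = np.asarray(acc, float)
    z = np.zeros_like(acc)
    return SweepResult(etas, z, z, acc, np.zeros((2, 2)), 0.5)


class TestMaa:
    def test_single_image_equals_best_accuracy(self):
        s = _fake_sweep([1, 2, 3], [0.8, 0.95, 0.9])
        value, eta = maa([s])
        assert value == 0.95 and eta == 2

    def test_crossing_curves_by_grid_scan(self):
        etas = [1, 2, 3, 4]
        a = _fake_sweep(etas, [0.90, 0.92, 0.80, 0.70])
        b = _fake_sweep(etas, [0.70, 0.85, 0.95, 0.96])
        value, eta = maa([a, b])
        # exhaustive scan of the mean curve
        means = [(x + y) / 2 for x, y in zip(a.acc, b.acc)]
        assert value == max(means)
        assert eta == etas[int(np.argmax(means))]

    def test_constant_curves(self):
        s = _fake_sweep([1, 2], [0.9, 0.9])
        value, _ = maa([s, s])
        assert value == 0.9

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            maa([_fake_sweep([1, 2], [0.5, 0.5]), _fake_sweep([1, 3], [0.5, 0.5])])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            maa([])
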
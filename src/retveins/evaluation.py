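"""Pixel-level evaluation: confusion counts in the FOV, agreement criteria, ROC/AUC.

All counts are restricted to the field of view.  With the gold-standard
vessel map as one rater and the segmentation as the other:

    Sen = TP/(TP+FN)      Spe = TN/(TN+FP)      PPV = TP/(TP+FP)
    NPV = TN/(TN+FN)      Acc = (TP+TN)/|FOV|
    Kappa = (P(A) − P(E))/(1 − P(E))

where P(A) is the accuracy and P(E) the chance agreement from the two
raters' marginals.  The ROC curve is generated by sweeping the elongation
threshold η on a FIXED coarse mask — each η re-runs the refinement stage —
collecting (FPF, TPF) per η, anchoring with (0,0) and (1,1) and
integrating by the trapezoidal rule.  The operating η for a dataset is the
one maximizing the across-image mean accuracy (MAA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask
from .refine import LineBank, build_line_bank, elongate, postprocess

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "SweepResult",
    "confusion",
    "criteria",
    "roc_sweep",
    "maa",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_fov(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SweepResult:
    """Per-η refinement outcomes on one image."""

    etas: np.ndarray
    tpf: np.ndarray
    fpf: np.ndarray
    acc: np.ndarray
    roc_points: np.ndarray  # (k, 2) anchored, FPF-sorted (FPF, TPF)
    auc: float


@dataclass
class EvalReport:
    """The scalar criteria for one image, plus the optional η-sweep curve."""

    sen: float
    spe: float
    ppv: float
    npv: float
    acc: float
    kappa: float
    sweep: SweepResult | None = None

    @property
    def roc_points(self) -> np.ndarray | None:
        return None if self.sweep is None else self.sweep.roc_points

    @property
    def auc(self) -> float | None:
        return None if self.sweep is None else self.sweep.auc


def confusion(pred: BinaryMask, gold: BinaryMask, fov: BinaryMask | None = None) -> ConfusionCounts:
    """Count TP/FP/TN/FN over FOV pixels only."""
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gold.shape}")
    if fov is None:
        fov = np.ones(pred.shape, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if fov.shape != pred.shape:
        raise ValueError("fov shape differs from prediction shape")
    p, g = pred[fov], gold[fov]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def criteria(counts: ConfusionCounts) -> EvalReport:
    """The six scalar criteria; undefined ratios are NaN with a warning."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.n_fov
    if n == 0:
        raise ValueError("empty FOV")
    acc = (tp + tn) / n
    p_pred_pos, p_gold_pos = (tp + fp) / n, (tp + fn) / n
    p_e = p_pred_pos * p_gold_pos + (1 - p_pred_pos) * (1 - p_gold_pos)
    kappa = 1.0 if p_e == 1.0 else (acc - p_e) / (1.0 - p_e)
    return EvalReport(
        sen=_ratio(tp, tp + fn, "sensitivity"),
        spe=_ratio(tn, tn + fp, "specificity"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        acc=acc,
        kappa=kappa,
    )


def anchored_auc(fpf: np.ndarray, tpf: np.ndarray) -> tuple[np.ndarray, float]:
    """Sort by FPF, anchor with (0,0) and (1,1), integrate by trapezoids."""
    order = np.argsort(fpf, kind="stable")
    pts = np.column_stack([fpf[order], tpf[order]])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    return pts, float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_sweep(
    premask: BinaryMask,
    gold: BinaryMask,
    fov: BinaryMask | None,
    etas: np.ndarray,
    bank: LineBank | None = None,
    area_min: int = 40,
    axis_ratio: float = 0.3,
    major_max: float = 40.0,
    rule: str = "minor-over-major",
    apply_postprocess: bool = True,
) -> SweepResult:
    """Re-run elongation (+ post-processing) per η on a fixed coarse mask.

    ``premask`` is the coarse segmentation after isolated-pixel removal;
    the coarse threshold is NOT re-derived, only the refinement varies.
    """
    etas = np.asarray(etas, dtype=np.float64)
    if etas.size == 0 or np.any(etas <= 0):
        raise ValueError("etas must be non-empty and positive")
    if bank is None:
        bank = build_line_bank()
    tpf, fpf, acc = [], [], []
    for eta in etas:
        mask = elongate(premask, bank, float(eta))
        if apply_postprocess:
            mask = postprocess(mask, area_min, axis_ratio, major_max, rule)
        c = confusion(mask, gold, fov)
        tpf.append(_ratio(c.tp, c.tp + c.fn, "TPF"))
        fpf.append(1.0 - _ratio(c.tn, c.tn + c.fp, "FPF"))
        acc.append((c.tp + c.tn) / c.n_fov)
    tpf, fpf, acc = np.array(tpf), np.array(fpf), np.array(acc)
    pts, auc = anchored_auc(fpf, tpf)
    return SweepResult(etas=etas, tpf=tpf, fpf=fpf, acc=acc, roc_points=pts, auc=auc)


def maa(sweeps: list[SweepResult]) -> tuple[float, float]:
    """Maximum average accuracy over a shared η grid.

    Returns ``(maa_value, argmax_eta)``: the best across-image mean
    accuracy and the η achieving it.
    """
    if len(sweeps) == 0:
        raise ValueError("need at least one sweep")
    grid = sweeps[0].etas
    for s in sweeps[1:]:
        if s.etas.shape != grid.shape or not np.allclose(s.etas, grid):
            raise ValueError("all sweeps must share the same eta grid")
    mean_acc = np.mean([s.acc for s in sweeps], axis=0)
    best = int(np.argmax(mean_acc))
    return float(mean_acc[best]), float(grid[best])
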
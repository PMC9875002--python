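"""Training loss, overlap metrics, DSC summaries and paired model comparison.

The loss is the smoothed soft-Dice form

    loss = 1 - (2 * sum(x*y) + 1) / (sum(x^2) + sum(y^2) + 1)

with the smoothing constant exactly 1, defined on real-valued prediction
and target (so mixup's soft masks are well-posed). Evaluation uses the
five pixel-wise ratios DSC, JI, sensitivity, specificity and accuracy
computed from a 2x2 confusion tally, with undefined ratios (zero
denominator) excluded from aggregates and logged rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .autodiff import Tensor

log = logging.getLogger(__name__)

METRIC_NAMES = ("DSC", "JI", "Sen", "Spe", "Acc")


def dice_loss(prediction, target) -> float:
    """Smoothed soft-Dice loss on real-valued masks in [0, 1]."""
    x = np.asarray(prediction, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {x.shape} vs target {y.shape}")
    num = 2.0 * float((x * y).sum()) + 1.0
    den = float((x * x).sum()) + float((y * y).sum()) + 1.0
    return 1.0 - num / den


def dice_loss_graph(prediction: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable per-sample soft-Dice loss, averaged over the batch.

    ``prediction``: (N, 1, H, W) graph tensor; ``target``: matching array.
    """
    y = Tensor(np.asarray(target, dtype=float))
    if prediction.shape != y.shape:
        raise ValueError(
            f"shape mismatch: prediction {prediction.shape} vs target {y.shape}"
        )
    axes = tuple(range(1, len(prediction.shape)))
    num = (prediction * y).sum(axis=axes) * 2.0 + 1.0
    den = (prediction * prediction).sum(axis=axes) + (y * y).sum(axis=axes) + 1.0
    return (1.0 - num / den).mean()


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(prediction_binary, target) -> ConfusionCounts:
    """Pixel-by-pixel 2x2 tally of a binary prediction against ground truth."""
    p = np.asarray(prediction_binary)
    t = np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    for name, a in (("prediction", p), ("target", t)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} is not binary; threshold upstream at 0.5")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        TP=int((p & t).sum()),
        FP=int((p & ~t).sum()),
        TN=int((~p & ~t).sum()),
        FN=int((~p & t).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """DSC, JI, Sen, Spe, Acc from counts; ``None`` where undefined."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "DSC": ratio(2 * tp, fn + fp + 2 * tp),
        "JI": ratio(tp, fp + fn + tp),
        "Sen": ratio(tp, fn + tp),
        "Spe": ratio(tn, tn + fp),
        "Acc": ratio(tp + tn, tp + fn + fp + tn),
    }


@dataclass
class MetricReport:
    """Per-image metrics plus mean +/- population-std aggregates (percent)."""

    per_image: list[dict[str, float | None]]
    aggregate: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_masks(cls, predictions, targets, ids=None) -> "MetricReport":
        per = [metrics(confusion(p, t)) for p, t in zip(predictions, targets)]
        return cls.from_per_image(per)

    @classmethod
    def from_per_image(cls, per_image) -> "MetricReport":
        report = cls(per_image=list(per_image))
        for name in METRIC_NAMES:
            vals = [m[name] for m in report.per_image if m[name] is not None]
            n_undef = len(report.per_image) - len(vals)
            report.n_undefined[name] = n_undef
            if n_undef:
                log.warning("%d image(s) had undefined %s; excluded from aggregate",
                            n_undef, name)
            if vals:
                arr = np.asarray(vals)
                report.aggregate[name] = (
                    100.0 * float(arr.mean()),
                    100.0 * float(arr.std()),   # population std over images
                )
        return report

    def format_row(self, name: str) -> str:
        mean, std = self.aggregate[name]
        return f"{mean:.1f} ± {std:.1f}"


def dsc_distribution(per_image_dsc, k: int = 10, ids=None) -> dict:
    """Bin DSC values (<0.7, 0.7-0.9, >=0.9) and list the top/bottom k.

    Ties are broken by image id so the ranking is deterministic.
    """
    vals = list(per_image_dsc)
    if not vals:
        raise ValueError("empty DSC list")
    if k > len(vals):
        raise ValueError(f"k={k} exceeds list length {len(vals)}")
    if ids is None:
        ids = list(range(len(vals)))
    order = sorted(zip(vals, ids), key=lambda t: (t[0], t[1]))
    arr = np.asarray(vals)
    return {
        "bins": (
            int((arr < 0.7).sum()),
            int(((arr >= 0.7) & (arr < 0.9)).sum()),
            int((arr >= 0.9).sum()),
        ),
        "top_k": [v for v, _ in order[::-1][:k]],
        "bottom_k": [v for v, _ in order[:k]],
        "top_k_ids": [i for _, i in order[::-1][:k]],
        "bottom_k_ids": [i for _, i in order[:k]],
    }


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    p_value: float
    significance_band: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.significance_band != significance_band(self.p_value):
            raise ValueError("band inconsistent with p-value")


def significance_band(p: float) -> str:
    """Star notation with cuts at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(dsc_a, dsc_b, model_a: str = "A", model_b: str = "B"
                   ) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on per-image DSC.

    Zero differences are dropped; exact null distribution for n <= 25
    effective pairs, normal approximation with tie correction above.
    """
    a = np.asarray(dsc_a, dtype=float)
    b = np.asarray(dsc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired DSC lists must be 1D and of equal length")
    if len(a) < 5:
        raise ValueError(f"need at least 5 paired images, got {len(a)}")
    diffs = a - b
    nonzero = np.count_nonzero(diffs)
    if nonzero == 0:
        return ComparisonResult(model_a, model_b, 1.0, "ns")
    method = "exact" if nonzero <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method=method)
        p = float(res.pvalue)
    except ValueError:
        # exact method refuses ties among the nonzero differences
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method="approx")
        p = float(res.pvalue)
    p = min(p, 1.0)
    return ComparisonResult(model_a, model_b, p, significance_band(p))
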
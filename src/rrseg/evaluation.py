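"""Segmentation metric suite: Dice, Jaccard, per-image ROC/AUC, R² agreement.

Dice = 2|P∩T| / (|P|+|T|) and Jaccard = |P∩T| / |P∪T| over pixel sets are
*undefined* (zero denominator) when prediction and truth are both empty —
which, for an image genuinely free of objects, corresponds to a perfect
segmentation. Two aggregation policies handle this:

* ``exclude`` (primary): undefined images are dropped from the mean;
* ``set_to_one``: undefined values are counted as 1.0, crediting the model
  for correctly segmenting nothing (at the cost of a spurious mode at 1.0
  in score histograms).

ROC curves are computed per image over all pixels of the probability map
and averaged *vertically*: each curve's TPR is interpolated onto a fixed
grid of FPR values and the mean and standard deviation taken per grid
point. The headline AUC is the mean of per-image AUCs (the area under the
mean curve is also reported). Images whose truth contains a single class
have no ROC and are excluded, mirroring the Dice policy.

"R²" between truth-derived and model-derived measurement vectors is the
squared Pearson correlation — the strength-of-correlation reading used on
measurement scatter plots. A coefficient-of-determination-against-identity
mode (``mode="identity"``) is available; the two differ whenever the points
sit off the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .io_formats import ClassMasks, InputError
from .morphometrics import measure_dataset
from .unet import ProbabilityMaps

CLASSES = ("rod", "ring")

EmptyPolicy = Literal["exclude", "set_to_one"]

#: measurement columns compared between truth- and model-derived tables
R2_COLUMNS = [
    "n_rods", "n_rings",
    "rod_mean_area_um2", "rod_mean_perimeter_um", "rod_perimeter_area_ratio",
    "ring_mean_area_um2", "ring_mean_perimeter_um", "ring_perimeter_area_ratio",
    "rod_ring_ratio",
]


class NoEvaluableImages(ValueError):
    """All values undefined under the exclude policy — nothing to average."""


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise InputError("ROC fpr/tpr must be nondecreasing")


@dataclass
class MeanROC:
    """Vertically averaged ROC: mean and sd of TPR on a fixed FPR grid."""

    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    mean_auc: float           # mean of per-image AUCs (primary)
    auc_of_mean_curve: float  # trapezoid under the averaged curve
    n_curves: int


@dataclass
class MetricsRecord:
    """Per-image pixel metrics; None marks an undefined (both-empty) value."""

    id: str
    dice: dict[str, float | None]
    jaccard: dict[str, float | None]
    auc: dict[str, float | None]


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise InputError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def dice(pred: np.ndarray, truth: np.ndarray) -> float | None:
    """2|P∩T| / (|P|+|T|); None when both masks are empty."""
    pred, truth = _check_shapes(pred, truth)
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return None
    return 2.0 * int((pred & truth).sum()) / denom


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float | None:
    """|P∩T| / |P∪T|; None when the union is empty."""
    pred, truth = _check_shapes(pred, truth)
    union = int((pred | truth).sum())
    if union == 0:
        return None
    return int((pred & truth).sum()) / union


def aggregate_metric(values: Sequence[float | None],
                     policy: EmptyPolicy = "exclude") -> tuple[float, float]:
    """Mean and sample SD of per-image metrics under an empty-mask policy."""
    if policy == "set_to_one":
        vals = [1.0 if v is None else float(v) for v in values]
    elif policy == "exclude":
        vals = [float(v) for v in values if v is not None]
        if not vals:
            raise NoEvaluableImages(
                "no evaluable images: every value is undefined under the "
                "exclude policy")
    else:
        raise InputError(f"unknown empty-mask policy {policy!r}")
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCCurve | None:
    """Per-pixel ROC of a class probability map against its truth mask.

    Returns None when the truth contains a single class (AUC undefined).
    The trapezoidal AUC equals the Mann–Whitney pair-ordering probability
    P(score_pos > score_neg) + ½·P(tie).
    """
    truth = np.asarray(truth, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.shape != truth.shape:
        raise InputError("score map and truth mask shapes differ")
    if truth.all() or not truth.any():
        return None
    fpr, tpr, _ = _skm.roc_curve(truth.astype(int), scores)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


def mean_roc(curves: Sequence[ROCCurve], n_grid: int = 101) -> MeanROC:
    """Vertical averaging on an evenly spaced FPR grid."""
    if len(curves) == 0:
        raise NoEvaluableImages("no ROC curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    tpr_mean = tprs.mean(axis=0)
    tpr_sd = tprs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(grid)
    return MeanROC(
        fpr_grid=grid, tpr_mean=tpr_mean, tpr_sd=tpr_sd,
        mean_auc=float(np.mean([c.auc for c in curves])),
        auc_of_mean_curve=float(np.trapezoid(tpr_mean, grid)),
        n_curves=len(curves),
    )


def r2_agreement(truth_values: Sequence[float], model_values: Sequence[float],
                 mode: Literal["pearson", "identity"] = "pearson") -> float:
    """Agreement between truth- and model-derived measurement vectors.

    ``pearson`` (default): squared Pearson correlation, invariant to affine
    rescaling of either axis. ``identity``: 1 − SS_res/SS_tot of the model
    values against the identity line, penalising systematic offsets.
    """
    t = np.asarray(truth_values, dtype=float)
    m = np.asarray(model_values, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise InputError("truth and model vectors must be equal-length 1D")
    if len(t) < 3:
        raise InputError("need at least 3 paired values")
    if np.allclose(t, t[0]):
        raise InputError("truth vector is constant; correlation undefined")
    if mode == "identity":
        ss_res = float(((m - t) ** 2).sum())
        ss_tot = float(((t - t.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    if np.allclose(m, m[0]):
        return 0.0
    r, _ = stats.pearsonr(t, m)
    return float(r**2)


@dataclass
class EvaluationReport:
    per_image: list[MetricsRecord]
    aggregate: pd.DataFrame          # rows: metric×class; cols: mean, sd, n
    mean_roc: dict[str, MeanROC | None]
    r2: pd.DataFrame                 # measurement column -> r2, n
    policy: EmptyPolicy


def evaluate_dataset(predictions: Mapping[str, ClassMasks],
                     probability_maps: Mapping[str, ProbabilityMaps] | None,
                     truths: Mapping[str, ClassMasks],
                     pixel_size_um: float,
                     policy: EmptyPolicy = "exclude") -> EvaluationReport:
    """Full metric suite over matched prediction/truth mask collections.

    ``predictions`` and ``truths`` must share exactly the same image ids.
    Probability maps are optional (ROC/AUC are skipped without them). R² is
    computed per measurement column across images, pairing truth-derived and
    model-derived records and dropping images where either value is missing.
    """
    if set(predictions) != set(truths):
        raise InputError("prediction and truth ids do not match")
    ids = sorted(predictions)
    per_image: list[MetricsRecord] = []
    roc_curves: dict[str, list[ROCCurve]] = {c: [] for c in CLASSES}
    for i in ids:
        pred, truth = predictions[i], truths[i]
        d = {c: dice(pred.classes()[c], truth.classes()[c]) for c in CLASSES}
        j = {c: jaccard(pred.classes()[c], truth.classes()[c]) for c in CLASSES}
        a: dict[str, float | None] = {c: None for c in CLASSES}
        if probability_maps is not None and i in probability_maps:
            pm = probability_maps[i]
            for c in CLASSES:
                curve = roc_curve(getattr(pm, c), truth.classes()[c])
                if curve is not None:
                    a[c] = curve.auc
                    roc_curves[c].append(curve)
        per_image.append(MetricsRecord(id=i, dice=d, jaccard=j, auc=a))

    rows = []
    for metric in ("dice", "jaccard", "auc"):
        for c in CLASSES:
            values = [getattr(rec, metric)[c] for rec in per_image]
            if metric == "auc":
                # single-class images have no ROC; always excluded
                defined = [v for v in values if v is not None]
                if defined:
                    mean, sd = aggregate_metric(defined, "exclude")
                    rows.append((metric, c, mean, sd, len(defined)))
                continue
            try:
                mean, sd = aggregate_metric(values, policy)
            except NoEvaluableImages:
                continue
            n = len(values) if policy == "set_to_one" else \
                sum(v is not None for v in values)
            rows.append((metric, c, mean, sd, n))
    aggregate = pd.DataFrame(rows, columns=["metric", "class", "mean", "sd", "n"])

    rocs = {c: (mean_roc(roc_curves[c]) if roc_curves[c] else None)
            for c in CLASSES}

    truth_table = measure_dataset((truths[i], pixel_size_um) for i in ids)
    pred_table = measure_dataset((predictions[i], pixel_size_um) for i in ids)
    r2_rows = []
    for col in R2_COLUMNS:
        t, m = truth_table[col].to_numpy(float), pred_table[col].to_numpy(float)
        keep = ~(np.isnan(t) | np.isnan(m))
        if keep.sum() >= 3 and not np.allclose(t[keep], t[keep][0]):
            r2_rows.append((col, r2_agreement(t[keep], m[keep]), int(keep.sum())))
        else:
            r2_rows.append((col, np.nan, int(keep.sum())))
    r2 = pd.DataFrame(r2_rows, columns=["measurement", "r2", "n"])

    return EvaluationReport(per_image=per_image, aggregate=aggregate,
                            mean_roc=rocs, r2=r2, policy=policy)
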
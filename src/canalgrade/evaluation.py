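"""Agreement and discrimination statistics for stenosis grading.

Multiclass predictions are scored against the reference grading with
Cohen's quadratically weighted kappa; binary stenosis probabilities with
ROC/AUC, the Youden-optimal operating point, operating points matched to
a reader's sensitivity or specificity, and confusion-matrix summaries
(accuracy, PPV, NPV).  Confidence intervals come from a nonparametric
percentile bootstrap over IVD levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score, roc_curve

from .errors import DegenerateMetricError, ValidationError
from .volume import binarize_grades as binarize  # noqa: F401  (public re-export)

BOOTSTRAP_DEFAULT_B = 1000


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def j_index(self) -> float:
        """Youden's J = sensitivity + specificity − 1."""
        return self.sensitivity + self.specificity - 1.0


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR per threshold
    specificity: np.ndarray  # TNR per threshold
    auc: float

    def points(self) -> list[OperatingPoint]:
        return [OperatingPoint(float(t), float(se), float(sp))
                for t, se, sp in zip(self.thresholds, self.sensitivity,
                                     self.specificity)]


def quadratic_weighted_kappa(true_grades, predicted_grades) -> float:
    """Cohen's kappa with quadratic disagreement weights w_ij = (i−j)².

    κw = 1 − Σ w_ij O_ij / Σ w_ij E_ij, with O the observed and E the
    chance-expected (outer product of marginals) confusion proportions.
    Undefined when both vectors are constant: there is no chance
    disagreement to correct for.
    """
    t = np.asarray(true_grades)
    p = np.asarray(predicted_grades)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValidationError("need two equal-length nonempty grade vectors")
    if len(np.unique(t)) == 1 and len(np.unique(p)) == 1:
        raise DegenerateMetricError(
            "kappa undefined: both vectors are a single constant grade")
    labels = sorted(set(t.tolist()) | set(p.tolist()))
    return float(cohen_kappa_score(t, p, labels=labels, weights="quadratic"))


def roc_and_auc(probabilities, binary_labels) -> RocCurve:
    """ROC curve and AUC (Mann-Whitney normalisation, ties count half)."""
    y = np.asarray(binary_labels)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateMetricError("AUC undefined: only one class present")
    # keep every achievable operating point: matched points and tie rules
    # must scan the full set, not the convex-hull-pruned one
    fpr, tpr, thr = roc_curve(y, p, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=float(roc_auc_score(y, p)))


def youden_optimal(roc: RocCurve) -> OperatingPoint:
    """Operating point maximising J; ties resolve to the lowest threshold."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # roc_curve emits thresholds in decreasing order -> last index = lowest
    i = int(best[-1])
    return OperatingPoint(float(roc.thresholds[i]),
                          float(roc.sensitivity[i]),
                          float(roc.specificity[i]))


def match_operating_point(roc: RocCurve, target: float,
                          axis: str = "sensitivity") -> OperatingPoint:
    """Achievable point closest to ``target`` on one ROC axis.

    Used to compare the model with a human reader at that reader's
    sensitivity or specificity; ties resolve to the higher J.
    """
    if axis not in ("sensitivity", "specificity"):
        raise ValidationError("axis must be 'sensitivity' or 'specificity'")
    vals = roc.sensitivity if axis == "sensitivity" else roc.specificity
    dist = np.abs(vals - target)
    cand = np.flatnonzero(dist <= dist.min() + 1e-12)
    j = roc.sensitivity[cand] + roc.specificity[cand] - 1.0
    i = int(cand[int(np.argmax(j))])
    return OperatingPoint(float(roc.thresholds[i]),
                          float(roc.sensitivity[i]),
                          float(roc.specificity[i]))


def confusion_from_rates(sensitivity: float, specificity: float,
                         n_pos: int, n_neg: int) -> dict:
    """Reconstruct a 2×2 confusion matrix and summary metrics from rates.

    TP/TN are the rates scaled to the class counts and rounded to whole
    levels; accuracy, PPV and NPV follow from the counts, so published
    sensitivity/specificity plus class sizes determine them.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one positive and one negative")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    fn, fp = n_pos - tp, n_neg - tn
    if tp + fp == 0 or tn + fn == 0:
        raise DegenerateMetricError("no predicted positives (or negatives); "
                                    "PPV/NPV undefined")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / (n_pos + n_neg),
        "ppv": tp / (tp + fp),
        "npv": tn / (tn + fn),
    }


def bootstrap_ci(metric_fn, data: tuple, n_boot: int = BOOTSTRAP_DEFAULT_B,
                 seed: int = 0, ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling IVD levels with replacement.

    ``metric_fn`` takes the resampled columns of ``data`` (equal-length
    arrays) and returns a scalar; replicates where it is undefined are
    dropped, with a warning if more than 5% fail.
    """
    if n_boot < 100:
        raise ValidationError("need at least 100 bootstrap resamples")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric_fn(*(a[idx] for a in arrays)))
        except DegenerateMetricError:
            failed += 1
    if failed > 0.05 * n_boot:
        warnings.warn(f"bootstrap CI unstable: metric undefined on "
                      f"{failed}/{n_boot} replicates", stacklevel=2)
    if not values:
        raise DegenerateMetricError("metric undefined on every bootstrap replicate")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def multiclass_report(true_grades, predicted_grades, n_boot: int = BOOTSTRAP_DEFAULT_B,
                      seed: int = 0) -> dict:
    """κw with bootstrap CI plus the 4×4 confusion matrix."""
    t = np.asarray(true_grades)
    p = np.asarray(predicted_grades)
    kappa = quadratic_weighted_kappa(t, p)
    lo, hi = bootstrap_ci(quadratic_weighted_kappa, (t, p), n_boot, seed)
    return {
        "kappa_w": kappa,
        "kappa_w_ci": [lo, hi],
        "confusion": confusion_matrix(t, p, labels=[0, 1, 2, 3]).tolist(),
        "n": int(t.size),
    }


def binary_report(true_binary, probabilities, threshold: float | None = None,
                  reader_points: dict[str, dict] | None = None,
                  n_boot: int = BOOTSTRAP_DEFAULT_B, seed: int = 0) -> dict:
    """Full binary evaluation: AUC + CI, Youden point, matched points.

    ``reader_points`` maps a reader name to ``{"sensitivity": s,
    "specificity": p}``; for each, the model's closest matching operating
    point on both axes is reported.  If ``threshold`` is given the model
    is also evaluated at that fixed probability cut-off (flags are
    probability >= threshold).
    """
    y = np.asarray(true_binary)
    p = np.asarray(probabilities, dtype=float)
    roc = roc_and_auc(p, y)
    auc_lo, auc_hi = bootstrap_ci(lambda yy, pp: roc_and_auc(pp, yy).auc,
                                  (y, p), n_boot, seed)
    opt = youden_optimal(roc)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    report = {
        "auc": roc.auc,
        "auc_ci": [auc_lo, auc_hi],
        "n": int(y.size), "n_pos": n_pos, "n_neg": n_neg,
        "youden": {
            "threshold": opt.threshold, "sensitivity": opt.sensitivity,
            "specificity": opt.specificity, "j_index": opt.j_index,
            **confusion_from_rates(opt.sensitivity, opt.specificity,
                                   n_pos, n_neg),
        },
        "roc": {"thresholds": roc.thresholds.tolist(),
                "sensitivity": roc.sensitivity.tolist(),
                "specificity": roc.specificity.tolist()},
    }
    if threshold is not None:
        pred = (p >= threshold).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        report["at_threshold"] = {
            "threshold": threshold,
            "sensitivity": tp / n_pos,
            "specificity": tn / n_neg,
        }
    if reader_points:
        matched = {}
        for name, pt in reader_points.items():
            matched[name] = {}
            for axis in ("sensitivity", "specificity"):
                if axis in pt:
                    m = match_operating_point(roc, pt[axis], axis)
                    matched[name][f"matched_{axis}"] = {
                        "threshold": m.threshold,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "j_index": m.j_index,
                    }
        report["reader_matched"] = matched
    return report
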
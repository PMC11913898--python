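"""Random-forest grading of stenosis severity from the six level metrics.

Two models are trained on the per-level feature vectors (CSA, APD, FSL
and their mid-vertebral ratios):

* multiclass — predicts the ordinal severity grade 0–3; 208 trees,
  maximum depth 46, 1 sample per leaf, stratified tenfold CV;
* binary — predicts stenosis (grade 2–3) vs none (grade 0–1); 29 trees,
  maximum depth 72, 23 samples per leaf, standard tenfold CV.

Both use tenfold cross-validation with a 90-10 train/validation split;
model quality is always assessed on the pooled out-of-fold predictions.
Feature-ablation runs retrain with metric subsets to attribute the
contribution of each measurement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ValidationError
from .volume import binarize_grades

log = logging.getLogger(__name__)

FEATURES = ("csa", "apd", "fsl", "r_csa", "r_apd", "r_fsl")

#: Feature-ablation subsets; "No X" / "Only X" drop or keep both the
#: absolute and the relative variant of a metric.
ABLATION_SUBSETS: dict[str, tuple[str, ...]] = {
    "No CSA": ("apd", "fsl", "r_apd", "r_fsl"),
    "No APD": ("csa", "fsl", "r_csa", "r_fsl"),
    "No FSL": ("csa", "apd", "r_csa", "r_apd"),
    "Only CSA": ("csa", "r_csa"),
    "Only APD": ("apd", "r_apd"),
    "Only FSL": ("fsl", "r_fsl"),
    "Only absolute": ("csa", "apd", "fsl"),
    "Only relative": ("r_csa", "r_apd", "r_fsl"),
    "All variables": FEATURES,
}

N_FOLDS = 10


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters; fixed per classification mode."""

    mode: str  # "multiclass" | "binary"
    n_trees: int
    max_depth: int
    min_samples_leaf: int
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("multiclass", "binary"):
            raise ValidationError("mode must be 'multiclass' or 'binary'")
        if min(self.n_trees, self.max_depth, self.min_samples_leaf) < 1:
            raise ValidationError("all forest counts must be >= 1")

    @classmethod
    def multiclass(cls, seed: int = 0) -> "ForestConfig":
        return cls("multiclass", n_trees=208, max_depth=46,
                   min_samples_leaf=1, seed=seed)

    @classmethod
    def binary(cls, seed: int = 0) -> "ForestConfig":
        return cls("binary", n_trees=29, max_depth=72,
                   min_samples_leaf=23, seed=seed)

    def make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf, random_state=seed)


@dataclass
class CVResult:
    """Pooled tenfold cross-validation output.

    ``oof_predictions`` holds the predicted grade (multiclass) or the
    stenosis probability (binary) for every record, each produced by the
    one model that did not see that record's fold during training.
    """

    config: ForestConfig
    features: tuple[str, ...]
    index: np.ndarray            # row indices of the records used
    y_true: np.ndarray           # grade (multiclass) or binary flag
    oof_predictions: np.ndarray
    fold_assignments: np.ndarray
    models: list = field(default_factory=list, repr=False)
    n_dropped: int = 0


def _complete_rows(features: pd.DataFrame, subset: tuple[str, ...]) -> pd.DataFrame:
    cols = list(subset) + ["grade"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    complete = features.dropna(subset=cols)
    dropped = len(features) - len(complete)
    if dropped:
        log.info("excluding %d records with incomplete features", dropped)
    return complete


def cross_validate(features: pd.DataFrame, config: ForestConfig,
                   subset: tuple[str, ...] = FEATURES) -> CVResult:
    """Tenfold CV with out-of-fold predictions for every complete record.

    Multiclass folds are stratified by grade to balance the rarer severe
    grades; binary folds are plain shuffled splits.  Records with missing
    ratios are excluded (not imputed).  Deterministic given the seed.
    """
    if not subset:
        raise ValidationError("feature subset must be non-empty")
    complete = _complete_rows(features, tuple(subset))
    if len(complete) < N_FOLDS:
        raise ValidationError(
            f"{len(complete)} complete records < {N_FOLDS} folds")
    X = complete[list(subset)].to_numpy(dtype=float)
    grades = complete["grade"].to_numpy(dtype=int)
    y = grades if config.mode == "multiclass" else binarize_grades(grades)

    if len(np.unique(y)) == 1:
        warnings.warn("all labels identical; predictions are that label",
                      stacklevel=2)

    if config.mode == "multiclass" and len(np.unique(y)) > 1:
        splitter = StratifiedKFold(N_FOLDS, shuffle=True, random_state=config.seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(N_FOLDS, shuffle=True, random_state=config.seed)
        splits = splitter.split(X)

    oof = np.empty(len(y), dtype=float)
    folds = np.empty(len(y), dtype=int)
    models = []
    for k, (tr, va) in enumerate(splits):
        forest = config.make_forest(seed=config.seed + k)
        forest.fit(X[tr], y[tr])
        if config.mode == "binary":
            if forest.n_classes_ == 1:
                oof[va] = float(forest.classes_[0])
            else:
                pos = int(np.flatnonzero(forest.classes_ == 1)[0])
                oof[va] = forest.predict_proba(X[va])[:, pos]
        else:
            oof[va] = forest.predict(X[va])
        folds[va] = k
        models.append(forest)
    return CVResult(config=config, features=tuple(subset),
                    index=complete.index.to_numpy(), y_true=y,
                    oof_predictions=oof, fold_assignments=folds,
                    models=models, n_dropped=len(features) - len(complete))


def train(features: pd.DataFrame, config: ForestConfig,
          subset: tuple[str, ...] = FEATURES) -> dict:
    """Fit one forest on all complete records; returns a model bundle."""
    complete = _complete_rows(features, tuple(subset))
    X = complete[list(subset)].to_numpy(dtype=float)
    grades = complete["grade"].to_numpy(dtype=int)
    y = grades if config.mode == "multiclass" else binarize_grades(grades)
    forest = config.make_forest(seed=config.seed)
    forest.fit(X, y)
    return {
        "model": forest,
        "manifest": {
            "config": asdict(config),
            "features": list(subset),
            "n_records": int(len(complete)),
        },
    }


def predict_binary(model: RandomForestClassifier, features: pd.DataFrame,
                   subset: tuple[str, ...] = FEATURES,
                   threshold: float = 0.46) -> pd.DataFrame:
    """Stenosis probabilities and flags (probability >= threshold).

    Records with incomplete features get NaN probability and a null flag.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    out = features[["study_id", "level"]].copy() \
        if {"study_id", "level"} <= set(features.columns) else pd.DataFrame(
            index=features.index)
    prob = np.full(len(features), np.nan)
    ok = features[list(subset)].notna().all(axis=1).to_numpy()
    if ok.any():
        X = features.loc[ok, list(subset)].to_numpy(dtype=float)
        if model.n_classes_ == 1:
            prob[ok] = float(model.classes_[0])
        else:
            pos = int(np.flatnonzero(model.classes_ == 1)[0])
            prob[ok] = model.predict_proba(X)[:, pos]
    out["probability"] = prob
    out["stenosis"] = pd.array(
        np.where(np.isnan(prob), pd.NA, prob >= threshold), dtype="boolean")
    return out


def predict_multiclass(model: RandomForestClassifier, features: pd.DataFrame,
                       subset: tuple[str, ...] = FEATURES) -> pd.DataFrame:
    out = features[["study_id", "level"]].copy() \
        if {"study_id", "level"} <= set(features.columns) else pd.DataFrame(
            index=features.index)
    pred = np.full(len(features), np.nan)
    ok = features[list(subset)].notna().all(axis=1).to_numpy()
    if ok.any():
        X = features.loc[ok, list(subset)].to_numpy(dtype=float)
        pred[ok] = model.predict(X)
    out["grade_pred"] = pred
    return out


def ablation_suite(features: pd.DataFrame, seed: int = 0,
                   n_boot: int = 1000,
                   subsets: dict[str, tuple[str, ...]] | None = None
                   ) -> pd.DataFrame:
    """Run multiclass κw and binary AUC for each feature subset.

    One CV per subset per mode; CIs from bootstrap over out-of-fold
    predictions.  Returns a table indexed by subset name.
    """
    from .evaluation import bootstrap_ci, quadratic_weighted_kappa, roc_and_auc

    rows = []
    for name, subset in (subsets or ABLATION_SUBSETS).items():
        mc = cross_validate(features, ForestConfig.multiclass(seed), subset)
        kappa = quadratic_weighted_kappa(mc.y_true, mc.oof_predictions.astype(int))
        k_lo, k_hi = bootstrap_ci(quadratic_weighted_kappa,
                                  (mc.y_true, mc.oof_predictions.astype(int)),
                                  n_boot=n_boot, seed=seed)
        bc = cross_validate(features, ForestConfig.binary(seed), subset)
        auc = roc_and_auc(bc.oof_predictions, bc.y_true).auc
        a_lo, a_hi = bootstrap_ci(lambda y, p: roc_and_auc(p, y).auc,
                                  (bc.y_true, bc.oof_predictions),
                                  n_boot=n_boot, seed=seed)
        rows.append({"subset": name, "n_features": len(subset),
                     "kappa_w": kappa, "kappa_w_lo": k_lo, "kappa_w_hi": k_hi,
                     "auc": auc, "auc_lo": a_lo, "auc_hi": a_hi})
    return pd.DataFrame(rows).set_index("subset")
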
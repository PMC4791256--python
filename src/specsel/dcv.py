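"""Double (nested) cross-validation for feature-subset selection.

Single cross-validation both tunes a classifier and scores it on the same
splits, so the reported error is optimistically biased.  The double CV
scheme here avoids that: an *inner* CV, run only on each outer-training
set, tunes the method's parameter (the NSC shrinkage threshold Delta, or
the SVM cost C together with the RFE subset size N), and the *outer* loop
measures misclassification on held-out samples that took no part in any
tuning decision.  The outer-fold predictions are pooled into a confusion
matrix from which accuracy and one-vs-rest sensitivity/specificity are
derived.  Finally the same inner tuning procedure is applied once to the
full data set to fix the reported optimal subset size N and the selected
feature list; the DCV error remains the honest performance estimate for
that selection protocol.

Optimal-subset rules: for SVM-RFE, the smallest N attaining the minimum
mean inner-CV error; for NSC, the subset minimizing the error and, among
ties, maximizing the summed probability assigned to the true class of the
inner-validation samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from . import nsc as _nsc
from . import rfe as _rfe
from .counts import SampleAnnotation, SpectralCountMatrix, relative_abundance, zscore_rows
from .ranking import RankedFeatureList

__all__ = [
    "DCVConfig",
    "DCVReport",
    "SubsetRecord",
    "run_dcv",
    "select_optimal_subset",
    "performance_metrics",
    "assign_protein_class",
]


class StratificationError(ValueError):
    """An outer training fold does not contain every class."""


@dataclass(frozen=True)
class DCVConfig:
    """Settings for one double-CV run."""

    method: Literal["nsc", "svm_rfe"]
    outer_folds: int | Literal["loo"] = 6
    inner_folds: int = 5
    seed: int = 0
    feature_scale: Literal["relative", "counts", "zscore"] = "relative"
    # NSC tuning
    n_delta: int = 30
    size_factor: Literal["minus", "plus"] = "minus"
    priors: Literal["empirical", "uniform"] = "empirical"
    # SVM-RFE tuning
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    step_fraction: float = 0.1
    exact_below: int = 200
    candidate_n: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("nsc", "svm_rfe"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.inner_folds < 2:
            raise ValueError("inner folds must be >= 2")
        if self.outer_folds != "loo" and self.outer_folds < 3:
            raise ValueError("outer folds must be >= 3 (or 'loo')")


@dataclass(frozen=True)
class SubsetRecord:
    """Inner-CV summary for one candidate tuning point."""

    n_features: int
    mean_error: float
    true_prob_sum: float = float("nan")
    param: float = float("nan")   # Delta (nsc) or C (svm_rfe)


@dataclass(frozen=True)
class FoldRecord:
    """What one outer fold decided and predicted."""

    fold: int
    test_runs: tuple[str, ...]
    tuning: dict
    true_labels: tuple[str, ...]
    predicted: tuple[str, ...]


@dataclass(frozen=True)
class DCVReport:
    config: DCVConfig
    classes: tuple[str, ...]
    outer_error: float
    accuracy: float
    optimal_n: int
    confusion: pd.DataFrame                  # rows true, columns predicted
    per_class_sensitivity: dict[str, float]
    per_class_specificity: dict[str, float]
    selected_features: RankedFeatureList
    class_assignment: pd.DataFrame
    fold_records: tuple[FoldRecord, ...] = field(default=(), repr=False)

    def to_text(self) -> str:
        lines = [f"# double cross-validation report ({self.config.method})"]
        cfg = self.config
        for key in sorted(vars(cfg)):
            lines.append(f"config.{key}\t{getattr(cfg, key)}")
        lines.append(f"outer_error\t{self.outer_error:.6g}")
        lines.append(f"accuracy\t{self.accuracy:.6g}")
        lines.append(f"optimal_n\t{self.optimal_n}")
        lines.append("## per-fold")
        for fr in self.fold_records:
            tuning = ", ".join(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
                               for k, v in sorted(fr.tuning.items()))
            err = float(np.mean(np.array(fr.predicted) != np.array(fr.true_labels)))
            lines.append(f"fold {fr.fold}\truns={','.join(fr.test_runs)}\t"
                         f"error={err:.6g}\t{tuning}")
        lines.append("## confusion (rows true, columns predicted)")
        lines.append(self.confusion.to_csv(sep="\t").rstrip("\n"))
        lines.append("## metrics")
        for c in self.classes:
            lines.append(f"sensitivity[{c}]\t{self.per_class_sensitivity[c]:.6g}")
            lines.append(f"specificity[{c}]\t{self.per_class_specificity[c]:.6g}")
        lines.append("## selected features (top optimal_n of final ranking)")
        lines.append(self.selected_features.to_frame().to_csv(sep="\t", index=False).rstrip("\n"))
        lines.append("## class assignment")
        lines.append(self.class_assignment.to_csv(sep="\t", index=False).rstrip("\n"))
        return "\n".join(lines) + "\n"


def _features(m: SpectralCountMatrix, scale: str) -> np.ndarray:
    """Samples-by-features matrix on the configured scale.

    Relative abundances are per-run (per-column) operations, so outer-test
    samples never influence training-fold statistics.
    """
    if scale == "relative":
        return relative_abundance(m).T
    if scale == "counts":
        return m.counts.T.astype(float)
    if scale == "zscore":
        return zscore_rows(m).T
    raise ValueError(f"unknown feature scale {scale!r}")


def _outer_splits(labels: np.ndarray, cfg: DCVConfig):
    if cfg.outer_folds == "loo":
        splitter = LeaveOneOut()
        splits = list(splitter.split(labels.reshape(-1, 1)))
    else:
        skf = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True,
                              random_state=cfg.seed)
        splits = list(skf.split(labels.reshape(-1, 1), labels))
    classes = set(labels)
    for train, _ in splits:
        if set(labels[train]) != classes:
            raise StratificationError("an outer training fold is missing a class")
    return splits


def _inner_splits(labels: np.ndarray, cfg: DCVConfig, seed: int):
    k = min(cfg.inner_folds, int(min(np.bincount(pd.factorize(labels)[0]))))
    k = max(k, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(labels.reshape(-1, 1), labels))


# --------------------------------------------------------------------------
# method-specific tuning on a training set


def _tune_nsc(X: np.ndarray, y: np.ndarray, cfg: DCVConfig, seed: int,
              feature_ids: tuple[str, ...]) -> tuple[dict, list[SubsetRecord]]:
    base = _nsc.fit_nsc(X, y, 0.0, feature_ids=feature_ids,
                        size_factor=cfg.size_factor, priors=cfg.priors)
    grid = _nsc.delta_grid(base, cfg.n_delta)
    errors = np.zeros(len(grid))
    probs = np.zeros(len(grid))
    n_val = 0
    for tr, va in _inner_splits(y, cfg, seed):
        for gi, delta in enumerate(grid):
            model = _nsc.fit_nsc(X[tr], y[tr], delta, feature_ids=feature_ids,
                                 size_factor=cfg.size_factor, priors=cfg.priors)
            pred, prob = _nsc.predict_nsc(model, X[va])
            errors[gi] += np.sum(pred != y[va])
            cls_idx = [model.classes.index(c) for c in y[va]]
            probs[gi] += prob[np.arange(len(va)), cls_idx].sum()
        n_val += len(va)
    records = []
    for gi, delta in enumerate(grid):
        at_delta = _nsc.fit_nsc(X, y, delta, feature_ids=feature_ids,
                                size_factor=cfg.size_factor, priors=cfg.priors)
        records.append(SubsetRecord(
            n_features=at_delta.n_active_features(),
            mean_error=errors[gi] / n_val,
            true_prob_sum=float(probs[gi]),
            param=float(delta),
        ))
    best = _select_record(records, "nsc")
    return {"delta": best.param, "n": best.n_features,
            "inner_error": best.mean_error}, records


def _svm_candidate_n(p: int, cfg: DCVConfig) -> list[int]:
    if cfg.candidate_n is not None:
        return sorted({n for n in cfg.candidate_n if 1 <= n <= p})
    grid = list(range(1, min(20, p) + 1)) + list(range(30, p + 1, 10))
    return sorted(set(grid))


def _tune_svm(X: np.ndarray, y: np.ndarray, cfg: DCVConfig, seed: int,
              feature_ids: tuple[str, ...]) -> tuple[dict, list[SubsetRecord]]:
    p = X.shape[1]
    n_grid = _svm_candidate_n(p, cfg)
    index = {f: i for i, f in enumerate(feature_ids)}
    per_c: dict[float, np.ndarray] = {}
    n_val = 0
    splits = _inner_splits(y, cfg, seed)
    for C in cfg.c_grid:
        errors = np.zeros(len(n_grid))
        for tr, va in splits:
            ranking = _rfe.rfe_rank(X[tr], y[tr], C=C,
                                    step_fraction=cfg.step_fraction,
                                    exact_below=cfg.exact_below,
                                    feature_ids=feature_ids).ranking
            for ni, n in enumerate(n_grid):
                cols = [index[f] for f in ranking[:n]]
                model = _rfe.train_linear_maxmargin(X[tr][:, cols], y[tr], C=C)
                pred = model.predict(X[va][:, cols])
                errors[ni] += np.sum(pred != y[va])
        per_c[C] = errors
    n_val = sum(len(va) for _, va in splits)
    records = [SubsetRecord(n_features=n, mean_error=per_c[C][ni] / n_val, param=C)
               for C in cfg.c_grid for ni, n in enumerate(n_grid)]
    best = _select_record(records, "svm_rfe")
    return {"C": best.param, "n": best.n_features,
            "inner_error": best.mean_error}, records


def _fit_predict(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray,
                 tuning: dict, cfg: DCVConfig,
                 feature_ids: tuple[str, ...]) -> np.ndarray:
    if cfg.method == "nsc":
        model = _nsc.fit_nsc(X_tr, y_tr, tuning["delta"], feature_ids=feature_ids,
                             size_factor=cfg.size_factor, priors=cfg.priors)
        pred, _ = _nsc.predict_nsc(model, X_te)
        return pred
    ranking = _rfe.rfe_rank(X_tr, y_tr, C=tuning["C"],
                            step_fraction=cfg.step_fraction,
                            exact_below=cfg.exact_below,
                            feature_ids=feature_ids).ranking
    index = {f: i for i, f in enumerate(feature_ids)}
    cols = [index[f] for f in ranking[: tuning["n"]]]
    model = _rfe.train_linear_maxmargin(X_tr[:, cols], y_tr, C=tuning["C"])
    return model.predict(X_te[:, cols])


def _final_ranking(X: np.ndarray, y: np.ndarray, tuning: dict, cfg: DCVConfig,
                   feature_ids: tuple[str, ...]) -> RankedFeatureList:
    if cfg.method == "nsc":
        model = _nsc.fit_nsc(X, y, tuning["delta"], feature_ids=feature_ids,
                             size_factor=cfg.size_factor, priors=cfg.priors)
        ranked = _nsc.rank_features_nsc(model)
        return ranked
    ranking = _rfe.rfe_rank(X, y, C=tuning["C"],
                            step_fraction=cfg.step_fraction,
                            exact_below=cfg.exact_below,
                            feature_ids=feature_ids)
    return ranking.to_ranked_list(n_selected=tuning["n"])


def run_dcv(m: SpectralCountMatrix, ann: SampleAnnotation,
            cfg: DCVConfig) -> DCVReport:
    """Run the full double-CV protocol on a (filtered) count matrix."""
    labels = ann.labels_for(m.run_ids)
    classes = ann.classes
    X = _features(m, cfg.feature_scale)
    feature_ids = m.protein_ids
    tune = _tune_nsc if cfg.method == "nsc" else _tune_svm

    fold_records = []
    true_all: list[str] = []
    pred_all: list[str] = []
    for fold, (tr, te) in enumerate(_outer_splits(labels, cfg)):
        tuning, _ = tune(X[tr], labels[tr], cfg, cfg.seed + 1 + fold, feature_ids)
        pred = _fit_predict(X[tr], labels[tr], X[te], tuning, cfg, feature_ids)
        fold_records.append(FoldRecord(
            fold=fold,
            test_runs=tuple(m.run_ids[i] for i in te),
            tuning=tuning,
            true_labels=tuple(labels[te]),
            predicted=tuple(pred),
        ))
        true_all.extend(labels[te])
        pred_all.extend(pred)

    confusion = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(true_all, pred_all):
        confusion.loc[t, p] += 1
    metrics = performance_metrics(confusion)

    final_tuning, _ = tune(X, labels, cfg, cfg.seed, feature_ids)
    ranked = _final_ranking(X, labels, final_tuning, cfg, feature_ids)
    ranked = RankedFeatureList(ranked.method_name, ranked.protein_ids,
                               ranked.scores, final_tuning["n"])
    assignment = assign_protein_class(m, ann, ranked)

    return DCVReport(
        config=cfg, classes=classes,
        outer_error=1.0 - metrics["accuracy"],
        accuracy=metrics["accuracy"],
        optimal_n=final_tuning["n"],
        confusion=confusion,
        per_class_sensitivity=metrics["sensitivity"],
        per_class_specificity=metrics["specificity"],
        selected_features=ranked,
        class_assignment=assignment,
        fold_records=tuple(fold_records),
    )


def _select_record(records: list[SubsetRecord], method: str) -> SubsetRecord:
    if not records:
        raise ValueError("no tuning records")
    best_err = min(r.mean_error for r in records)
    tied = [r for r in records if r.mean_error == best_err]
    if method == "nsc":
        best_prob = max(r.true_prob_sum for r in tied)
        tied = [r for r in tied if r.true_prob_sum == best_prob]
    return min(tied, key=lambda r: (r.n_features, r.param))


def select_optimal_subset(records: list[SubsetRecord],
                          method: Literal["nsc", "svm_rfe"]) -> int:
    """Apply the method's optimal-subset rule to inner-CV records.

    SVM-RFE: smallest N with minimal mean error.  NSC: minimal error,
    then maximal summed true-class probability, then smallest N.
    """
    return _select_record(records, method).n_features


def performance_metrics(confusion: pd.DataFrame | np.ndarray) -> dict:
    """One-vs-rest sensitivity/specificity and accuracy from a confusion
    matrix (rows = true class, columns = predicted class).

    A class never observed among the true labels has undefined
    sensitivity, reported as NaN.
    """
    if isinstance(confusion, pd.DataFrame):
        labels = list(confusion.index)
        cm = confusion.to_numpy(dtype=float)
    else:
        cm = np.asarray(confusion, dtype=float)
        labels = list(range(cm.shape[0]))
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be >= 0")
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    return {
        "accuracy": float(tp.sum() / total) if total else float("nan"),
        "sensitivity": {c: float(s) for c, s in zip(labels, sens)},
        "specificity": {c: float(s) for c, s in zip(labels, spec)},
    }


def assign_protein_class(m: SpectralCountMatrix, ann: SampleAnnotation,
                         selected: RankedFeatureList | list[str],
                         ) -> pd.DataFrame:
    """Associate each selected protein with one class and a direction.

    The decision-boundary rule: on relative abundances, compute each
    protein's standardized centroid deviation
    (xbar_ik - xbar_i)/(s_i + s0) per class; the protein belongs to the
    class of largest absolute deviation, "up" if that deviation is
    positive.  A protein with identical class means is flagged ambiguous.
    """
    ids = list(selected.selected) if isinstance(selected, RankedFeatureList) else list(selected)
    missing = [p for p in ids if p not in m.protein_ids]
    if missing:
        raise KeyError(f"selected proteins absent from matrix: {missing[:5]}")
    X = relative_abundance(m).T
    labels = ann.labels_for(m.run_ids)
    model = _nsc.fit_nsc(X, labels, 0.0, feature_ids=m.protein_ids)
    dev = model.d * model.class_size_factor[None, :]   # (xbar_ik - xbar_i)/(s_i+s0)
    index = {p: i for i, p in enumerate(m.protein_ids)}
    rows = []
    for pid in ids:
        i = index[pid]
        k = int(np.argmax(np.abs(dev[i])))
        top = dev[i, k]
        rows.append({
            "protein_id": pid,
            "class": model.classes[k] if top != 0 else "ambiguous",
            "direction": ("up" if top > 0 else "down") if top != 0 else "none",
            "deviation": float(top),
        })
    return pd.DataFrame(rows, columns=["protein_id", "class", "direction", "deviation"])
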
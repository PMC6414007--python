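"""Classifier evaluation harness.

Single features are evaluated with a linear threshold rule whose cut
point is selected by stratified five-fold cross-validation on the
training half of a patient-independent (recording-level) 50/50 split,
repeated with fresh random splits. Feature combinations are evaluated
with a weakly ridge-penalised binary logistic regression. All scaling
parameters (per-feature min/max mapped to [-1, 1]) come from the
training half only, so no statistic of the test set leaks into the
model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError, ParameterError
from .metrics import ConfusionCounts, confusion_metrics, f1_score, mcc
from .preprocessing import WHEEZE

OBJECTIVES = ("F1", "MCC")
#: ridge strength on logistic weights; subset search inevitably meets
#: linearly separable subsets, a weak penalty keeps weights finite
LOGISTIC_RIDGE = 1e-4


@dataclass(frozen=True)
class EvalConfig:
    folds: int = 5
    repetitions: int = 100
    objective: str = "F1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if self.objective not in OBJECTIVES:
            raise ParameterError(f"objective must be one of {OBJECTIVES}")


# ---------------------------------------------------------------------------
# feature scaling


@dataclass
class ScalingParams:
    """Per-feature training min/max for the affine map onto [-1, 1]."""

    features: list[str]
    mins: pd.Series
    maxs: pd.Series
    constant: list[str] = field(default_factory=list)


def fit_scaling(train: pd.DataFrame) -> ScalingParams:
    """Record per-feature min/max from the training set; constant
    features are flagged and excluded from classification."""
    if len(train) < 2:
        raise ParameterError("scaling needs at least 2 training events")
    mins, maxs = train.min(), train.max()
    constant = [c for c in train.columns if maxs[c] <= mins[c]]
    features = [c for c in train.columns if c not in constant]
    return ScalingParams(features=features,
                         mins=mins[features], maxs=maxs[features],
                         constant=constant)


def apply_scaling(data: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """x' = -1 + 2 (x - min) / (max - min). Test values outside the
    training range map outside [-1, 1]; no clipping."""
    missing = [f for f in params.features if f not in data.columns]
    if missing:
        raise ParameterError(f"features not in data: {missing}")
    x = data[params.features]
    return -1.0 + 2.0 * (x - params.mins) / (params.maxs - params.mins)


# ---------------------------------------------------------------------------
# recording-level splits


@dataclass(frozen=True)
class SplitPlan:
    train_recordings: tuple[str, ...]
    test_recordings: tuple[str, ...]
    seed: int


def split_by_recording(recording_ids, seed: int) -> SplitPlan:
    """Random patient-independent 50/50 partition by recording."""
    unique = sorted(set(map(str, recording_ids)))
    if len(unique) < 2:
        raise ParameterError("need at least 2 recordings to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = len(unique) // 2
    train = tuple(unique[i] for i in order[:n_train])
    test = tuple(unique[i] for i in order[n_train:])
    return SplitPlan(train_recordings=train, test_recordings=test, seed=seed)


# ---------------------------------------------------------------------------
# threshold sweep and rules


@dataclass(frozen=True)
class ThresholdRule:
    """A learned single-feature linear classifier. An event is called
    wheeze iff its (scaled) feature value is strictly beyond the
    threshold in the given direction; ties classify negative."""

    feature: str
    direction: str  # 'greater' | 'less'
    threshold: float

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "greater":
            return values > self.threshold
        return values < self.threshold


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive sorted unique values plus one sentinel
    below the minimum and one above the maximum (n_unique + 1 in all)."""
    u = np.unique(np.asarray(values, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _count_arrays(values, labels, thresholds):
    """Confusion counts at every candidate threshold for both
    directions; returns {direction: (tp, tn, fp, fn)} arrays."""
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    n_pos, n_neg = pos.size, neg.size
    pos_gt = n_pos - np.searchsorted(pos, thresholds, side="right")
    neg_gt = n_neg - np.searchsorted(neg, thresholds, side="right")
    pos_lt = np.searchsorted(pos, thresholds, side="left")
    neg_lt = np.searchsorted(neg, thresholds, side="left")
    return {
        "greater": (pos_gt, n_neg - neg_gt, neg_gt, n_pos - pos_gt),
        "less": (pos_lt, n_neg - neg_lt, neg_lt, n_pos - pos_lt),
    }


def _objective_array(tp, tn, fp, fn, objective: str) -> np.ndarray:
    tp, tn, fp, fn = (np.asarray(a, dtype=float) for a in (tp, tn, fp, fn))
    if objective == "F1":
        den = 2 * tp + fp + fn
        return np.where(den > 0, 2 * tp / np.maximum(den, 1e-300), 0.0)
    num = tp * tn - fp * fn
    margins = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return np.where(margins > 0, num / np.sqrt(np.maximum(margins, 1e-300)), 0.0)


def sweep_thresholds(values, labels):
    """All candidate (direction, threshold, ConfusionCounts) triples."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ParameterError("threshold sweep needs both classes")
    thresholds = candidate_thresholds(values)
    arrays = _count_arrays(values, labels, thresholds)
    out = []
    for direction in ("greater", "less"):
        tp, tn, fp, fn = arrays[direction]
        for i, t in enumerate(thresholds):
            out.append((direction, float(t),
                        ConfusionCounts(int(tp[i]), int(tn[i]), int(fp[i]), int(fn[i]))))
    return out


def crossval_threshold(
    values, labels, feature: str, cfg: EvalConfig, seed: int | None = None
) -> ThresholdRule:
    """Select the (direction, threshold) maximising the mean objective
    over stratified CV validation folds.

    Candidates come from the pooled training sweep. Ties break toward
    'greater' and then toward the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ParameterError("cross-validation needs both classes")
    n_min = min(labels.sum(), (~labels).sum())
    if n_min < cfg.folds:
        raise ParameterError(
            f"minority class has {n_min} events; cannot stratify {cfg.folds} folds"
        )
    thresholds = candidate_thresholds(values)
    obj = {d: np.zeros(thresholds.size) for d in ("greater", "less")}
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=(cfg.seed if seed is None else seed) % 2**31)
    for _, val_idx in skf.split(values.reshape(-1, 1), labels):
        arrays = _count_arrays(values[val_idx], labels[val_idx], thresholds)
        for d in obj:
            obj[d] += _objective_array(*arrays[d], cfg.objective)
    # argmax with deterministic tie-break: greater before less, small threshold
    all_obj = np.concatenate([obj["greater"], obj["less"]])
    all_dir = np.concatenate([np.zeros(thresholds.size), np.ones(thresholds.size)])
    all_thr = np.concatenate([thresholds, thresholds])
    best = np.lexsort((all_thr, all_dir, -all_obj))[0]
    return ThresholdRule(
        feature=feature,
        direction="greater" if all_dir[best] == 0 else "less",
        threshold=float(all_thr[best]),
    )


def evaluate_rule(rule: ThresholdRule, values, labels) -> ConfusionCounts:
    """Confusion counts of a threshold rule on labelled feature values."""
    labels = np.asarray(labels, dtype=bool)
    pred = rule.predict(values)
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


# ---------------------------------------------------------------------------
# repeated single-feature evaluation


@dataclass
class EvalReport:
    """Mean +/- SD of test metrics per feature over repeated splits."""

    table: pd.DataFrame
    objective: str
    config: EvalConfig


def _split_frames(table: pd.DataFrame, seed: int):
    plan = split_by_recording(table["recording_id"], seed)
    in_train = table["recording_id"].astype(str).isin(plan.train_recordings)
    train, test = table[in_train], table[~in_train]
    for part, name in ((train, "train"), (test, "test")):
        y = part["label"] == WHEEZE
        if y.all() or not y.any():
            raise ParameterError(f"{name} side of split {seed} has one class only")
    return train, test


def _feature_columns(table: pd.DataFrame, features=None) -> list[str]:
    cols = [c for c in table.columns if c not in ("recording_id", "label")]
    if features is None:
        return cols
    missing = [f for f in features if f not in cols]
    if missing:
        raise ParameterError(f"unknown features: {missing}")
    return list(features)


def repeated_evaluation(
    table: pd.DataFrame, cfg: EvalConfig, features=None
) -> EvalReport:
    """The single-feature benchmark: per repetition draw a fresh
    recording-level 50/50 split, fit scaling on the training half,
    CV-select a threshold per feature, and measure on the test half.
    """
    feats = _feature_columns(table, features)
    records: dict[str, dict[str, list]] = {
        f: {k: [] for k in ("SE", "SP", "PPV", "NPV", "objective", "threshold", "direction")}
        for f in feats
    }
    for rep in range(cfg.repetitions):
        split_seed = cfg.seed + rep
        train, test = _split_frames(table, split_seed)
        params = fit_scaling(train[feats])
        strain = apply_scaling(train, params)
        stest = apply_scaling(test, params)
        y_train = (train["label"] == WHEEZE).to_numpy()
        y_test = (test["label"] == WHEEZE).to_numpy()
        fold_seed = (cfg.seed * 100_003 + rep) % 2**31
        for f in params.features:
            rule = crossval_threshold(strain[f].to_numpy(), y_train, f, cfg, seed=fold_seed)
            counts = evaluate_rule(rule, stest[f].to_numpy(), y_test)
            m = confusion_metrics(counts)
            rec = records[f]
            for k in ("SE", "SP", "PPV", "NPV"):
                rec[k].append(m[k])
            rec["objective"].append(
                f1_score(counts) if cfg.objective == "F1" else mcc(counts))
            rec["threshold"].append(rule.threshold)
            rec["direction"].append(rule.direction)
    rows = []
    for f in feats:
        rec = records[f]
        if not rec["objective"]:
            continue  # constant in every split
        row: dict[str, object] = {"feature": f}
        for k in ("SE", "SP", "PPV", "NPV", "threshold", "objective"):
            arr = np.asarray(rec[k], dtype=float)
            key = cfg.objective if k == "objective" else k
            if np.isnan(arr).all():
                row[f"{key}_mean"] = float("nan")
                row[f"{key}_sd"] = float("nan")
            else:
                row[f"{key}_mean"] = float(np.nanmean(arr))
                row[f"{key}_sd"] = float(np.nanstd(arr)) if arr.size > 1 else 0.0
        greater = rec["direction"].count("greater")
        row["direction"] = "greater" if greater * 2 >= len(rec["direction"]) else "less"
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature")
    df = df.sort_values(f"{cfg.objective}_mean", ascending=False)
    return EvalReport(table=df, objective=cfg.objective, config=cfg)


# ---------------------------------------------------------------------------
# logistic regression over feature subsets


@dataclass
class LogisticModel:
    """Binary logistic regression over a scaled feature subset;
    prediction is wheeze iff fitted probability > 0.5."""

    features: list[str]
    weights: np.ndarray
    intercept: float
    _clf: LogisticRegression

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self._clf.predict_proba(data[self.features].to_numpy())[:, 1] > 0.5


def fit_logistic(train: pd.DataFrame, labels, features=None,
                 max_iter: int = 5000) -> LogisticModel:
    """Penalised-ML logistic fit (ridge lambda = 1e-4 on the weights)."""
    feats = list(features) if features is not None else list(train.columns)
    if not feats:
        raise ParameterError("fit_logistic needs at least one feature")
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ParameterError("fit_logistic needs both classes")
    clf = LogisticRegression(C=1.0 / LOGISTIC_RIDGE, solver="lbfgs", max_iter=max_iter)
    clf.fit(train[feats].to_numpy(), y)
    if int(np.max(clf.n_iter_)) >= max_iter:
        raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations")
    return LogisticModel(features=feats, weights=clf.coef_[0].copy(),
                         intercept=float(clf.intercept_[0]), _clf=clf)


def _objective_of_predictions(pred: np.ndarray, y: np.ndarray, objective: str) -> float:
    counts = ConfusionCounts(
        tp=int(np.sum(pred & y)), tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)), fn=int(np.sum(~pred & y)))
    val = f1_score(counts) if objective == "F1" else mcc(counts)
    return 0.0 if np.isnan(val) else float(val)


def combination_search(
    table: pd.DataFrame, sizes=(2, 3), cfg: EvalConfig | None = None, pool=None
) -> pd.DataFrame:
    """Exhaustive logistic-regression search over feature subsets.

    Every subset of each requested size from ``pool`` (default: all
    features) is fitted on the scaled training half and scored on the
    test half, averaged over ``cfg.repetitions`` splits. Returns a
    DataFrame ranked by mean objective, descending.
    """
    cfg = cfg or EvalConfig()
    feats = _feature_columns(table, pool)
    subsets = [c for size in sizes for c in itertools.combinations(feats, size)]
    sums = np.zeros(len(subsets))
    for rep in range(cfg.repetitions):
        train, test = _split_frames(table, cfg.seed + rep)
        params = fit_scaling(train[feats])
        strain, stest = apply_scaling(train, params), apply_scaling(test, params)
        y_train = (train["label"] == WHEEZE).to_numpy()
        y_test = (test["label"] == WHEEZE).to_numpy()
        usable = set(params.features)
        for i, subset in enumerate(subsets):
            sel = [f for f in subset if f in usable]
            if not sel:
                continue
            model = fit_logistic(strain, y_train, features=sel)
            sums[i] += _objective_of_predictions(model.predict(stest), y_test, cfg.objective)
    df = pd.DataFrame({
        "features": [" + ".join(s) for s in subsets],
        "size": [len(s) for s in subsets],
        cfg.objective: sums / cfg.repetitions,
    })
    return df.sort_values(cfg.objective, ascending=False).reset_index(drop=True)


def sequential_forward_selection(
    table: pd.DataFrame, max_size: int, cfg: EvalConfig | None = None, features=None
) -> pd.DataFrame:
    """Greedy forward selection with logistic regression.

    At each step the feature maximising the mean stratified-CV
    objective on the training half joins the subset; the objective on
    the held-out test half is reported alongside but never optimised.
    """
    cfg = cfg or EvalConfig()
    feats = _feature_columns(table, features)
    if max_size > len(feats):
        raise ParameterError("max_size exceeds the number of features")
    train, test = _split_frames(table, cfg.seed)
    params = fit_scaling(train[feats])
    strain, stest = apply_scaling(train, params), apply_scaling(test, params)
    y_train = (train["label"] == WHEEZE).to_numpy()
    y_test = (test["label"] == WHEEZE).to_numpy()
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed % 2**31)
    folds = list(skf.split(strain.to_numpy(), y_train))

    def cv_objective(subset: list[str]) -> float:
        vals = []
        for tr_idx, va_idx in folds:
            model = fit_logistic(strain.iloc[tr_idx], y_train[tr_idx], features=subset)
            vals.append(_objective_of_predictions(
                model.predict(strain.iloc[va_idx]), y_train[va_idx], cfg.objective))
        return float(np.mean(vals))

    selected: list[str] = []
    remaining = list(params.features)
    rows = []
    for size in range(1, max_size + 1):
        scored = [(cv_objective(selected + [f]), f) for f in remaining]
        best_obj, best_feat = max(scored, key=lambda t: (t[0], -remaining.index(t[1])))
        selected.append(best_feat)
        remaining.remove(best_feat)
        model = fit_logistic(strain, y_train, features=selected)
        test_obj = _objective_of_predictions(model.predict(stest), y_test, cfg.objective)
        rows.append({
            "size": size, "added": best_feat,
            f"cv_{cfg.objective}": best_obj, f"test_{cfg.objective}": test_obj,
            "subset": " + ".join(selected),
        })
    return pd.DataFrame(rows)
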
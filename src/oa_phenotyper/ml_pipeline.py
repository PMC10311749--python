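"""ML comparator pipeline: features, SMOTE, nested CV with RF-based feature
elimination, and Shapley feature attribution.

The learning task mirrors the published design: among patients with hip/knee
OA, separate "cases" (moderate-to-severe disease with inadequate analgesic
response) from "comparators" using claims-derived features. Because cases
outnumber comparators, training folds are rebalanced with SMOTE; features are
pruned by recursive elimination driven by random-forest importances; model
hyperparameters and the elimination threshold are tuned in the inner loop of
a nested cross-validation whose outer folds estimate generalization.

SMOTE here is the classic interpolation scheme: each synthetic minority row
is ``x + u * (nn - x)`` for a uniform ``u`` and ``nn`` one of the k nearest
minority neighbours (Euclidean distance on z-scored columns; the convex
combination itself is formed in raw feature space, which is equivalent up to
the affine scaling). It is applied strictly inside training partitions.

Shapley attributions are estimated by Monte-Carlo permutation sampling. For
every draw a background row and a feature permutation are sampled and the
telescoping marginal contributions are accumulated, so the per-sample
attributions sum exactly to ``f(x) - mean(f(background draws))`` (local
accuracy holds to floating point against that baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .cohort_builder import DateInterval, quan_charlson
from .evaluation import ConfusionMatrix, MetricSet, auc as _auc_map, f1 as _f1, metrics as _metrics
from .records_io import (
    CodeSet,
    DrugClass,
    PatientDB,
    Setting,
    match_code,
)

__all__ = [
    "FeatureMatrix",
    "MLConfig",
    "CVResult",
    "ShapReport",
    "extract_features",
    "smote",
    "rf_rfe",
    "nested_cv",
    "fit_model",
    "predict_proba",
    "mean_abs_shap",
    "DEFAULT_GRIDS",
]

#: diagnosis concepts turned into flag+count feature pairs
_DX_FEATURE_SETS = (
    "OA_HIP_KNEE", "JOINT_PAIN_HIP", "JOINT_PAIN_KNEE", "JOINT_PAIN_OTHER",
    "BACK_PAIN", "UNSPECIFIED_PAIN", "HYPERTENSION", "DIABETES", "GERD",
    "DEPRESSION", "ANXIETY", "DRUG_ALCOHOL_ABUSE", "INSOMNIA", "OBESITY",
)
#: procedure concepts turned into flag+count feature pairs
_PROC_FEATURE_SETS = (
    "IA_CORTICOSTEROID", "HA_INJECTION", "NERVE_BLOCK", "KNEE_ARTHROPLASTY",
    "HIP_ARTHROPLASTY", "XRAY_HIP_KNEE", "MRI_HIP_KNEE", "IMAGING_HIP_KNEE",
    "PT_OT", "MOBILITY_AID",
)


@dataclass
class FeatureMatrix:
    """Per-patient numeric features with boolean case/comparator labels."""

    X: pd.DataFrame
    y: pd.Series  # True = case (all three OA characteristics)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature matrix and labels are misaligned")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")


def extract_features(
    db: PatientDB,
    windows: Mapping[str, DateInterval],
    code_sets: Mapping[str, CodeSet],
) -> FeatureMatrix:
    """Deterministic feature extraction for the OA-positive subcohort.

    One binary flag + one event count per clinical concept, one flag + count
    per drug class, utilization counts per care setting, age at the study
    anchor, daily health-care cost (total reimbursed cost / window days), and
    the Charlson score. Only patients whose gold label shows hip/knee OA are
    included; the label is the composite case definition.
    """
    pids = [
        pid for pid in sorted(windows)
        if pid in db.labels and db.labels[pid].has_oa_hip_knee
    ]
    rows = []
    for pid in pids:
        rec = db.records[pid]
        window = windows[pid]
        if window.days() < 1:
            raise ValueError(f"patient {pid}: zero-length extraction window")
        feats: dict[str, float] = {}
        for name in _DX_FEATURE_SETS:
            cs = code_sets[name]
            n = sum(
                1 for d in rec.diagnoses
                if window.contains(d.date) and match_code(d.code, d.system, cs)
            )
            key = name.lower()
            feats[f"{key}_flag"] = float(n > 0)
            feats[f"{key}_count"] = float(n)
        for name in _PROC_FEATURE_SETS:
            cs = code_sets[name]
            n = sum(
                1 for p in rec.procedures
                if window.contains(p.date) and match_code(p.code, p.system, cs)
            )
            key = name.lower()
            feats[f"{key}_flag"] = float(n > 0)
            feats[f"{key}_count"] = float(n)
        for drug_class in DrugClass:
            n = sum(
                1 for f in rec.drugs
                if window.contains(f.fill_date) and f.drug_class is drug_class
            )
            key = drug_class.value.lower()
            feats[f"{key}_flag"] = float(n > 0)
            feats[f"{key}_count"] = float(n)
        for setting in Setting:
            feats[f"visits_{setting.value.lower()}"] = float(
                len({d.date for d in rec.diagnoses if window.contains(d.date) and d.setting is setting})
            )
        total_cost = sum(p.cost for p in rec.procedures if window.contains(p.date))
        total_cost += sum(f.cost for f in rec.drugs if window.contains(f.fill_date))
        feats["daily_healthcare_cost"] = total_cost / window.days()
        feats["age"] = float(window.start.year - (rec.birth_year or window.start.year))
        feats["charlson_score"] = float(quan_charlson(rec, window).score)
        rows.append(feats)
    X = pd.DataFrame(rows, index=pd.Index(pids, name="patient_id"))
    y = pd.Series([db.labels[p].is_case for p in pids], index=X.index, name="case")
    return FeatureMatrix(X=X, y=y)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Oversample the minority class with interpolated synthetic rows.

    Returns ``(X_out, y_out, synthetic_mask)`` where the original rows come
    first (unchanged) and the mask flags appended synthetic rows. The
    minority class is grown to ``target_ratio`` times the majority count.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    y_arr = y.to_numpy(dtype=bool)
    n_pos, n_neg = int(y_arr.sum()), int((~y_arr).sum())
    minority_label = n_pos < n_neg
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    n_target = int(round(target_ratio * n_maj))
    n_new = n_target - n_min
    mask_orig = np.zeros(len(y_arr), dtype=bool)
    if n_new <= 0:
        return X.copy(), y.copy(), mask_orig
    if n_min <= k:
        raise ValueError(
            f"minority class has {n_min} rows; SMOTE needs more than k={k} "
            "(reduce k)"
        )
    minority = X.to_numpy(dtype=float)[y_arr == minority_label]
    # neighbour search in z-scored space; interpolation in raw space
    mu = minority.mean(axis=0)
    sd = minority.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (minority - mu) / sd
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1)[:, :k]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    neighbors = minority[nn_idx[base, pick]]
    synthetic = minority[base] + u[:, None] * (neighbors - minority[base])

    X_syn = pd.DataFrame(
        synthetic,
        columns=X.columns,
        index=pd.Index([f"synthetic_{i}" for i in range(n_new)], name=X.index.name),
    )
    X_out = pd.concat([X, X_syn])
    y_out = pd.concat(
        [y, pd.Series([bool(minority_label)] * n_new, index=X_syn.index, name=y.name)]
    )
    mask = np.concatenate([mask_orig, np.ones(n_new, dtype=bool)])
    return X_out, y_out, mask


# ---------------------------------------------------------------------------
# RF-driven recursive feature elimination
# ---------------------------------------------------------------------------


def _importance_order(X: pd.DataFrame, y: pd.Series, seed: int) -> list[str]:
    rf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y.to_numpy(dtype=int))
    # least important first; importance ties broken by dropping the
    # lexicographically-last feature name first
    pairs = sorted(zip(rf.feature_importances_, X.columns), key=lambda t: (t[0], _revkey(t[1])))
    return [name for _, name in pairs]


def _revkey(name: str) -> tuple:
    # sort key that reverses lexicographic order
    return tuple(-ord(c) for c in name)


def rfe_path(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    min_features: int = 1,
    drop_frac: float = 0.2,
) -> list[str]:
    """Elimination order as a ranked feature list (best retained last-dropped).

    Returns feature names ordered from most to least persistent: the
    selection at threshold ``t`` is the first ``t`` names. Each iteration
    refits the random-forest ranker and drops the least-important fraction
    (at least one feature) of the surviving set.
    """
    surviving = list(X.columns)
    eliminated: list[str] = []
    it = 0
    while len(surviving) > min_features:
        order = _importance_order(X[surviving], y, seed + it)
        n_drop = max(1, int(drop_frac * len(surviving)))
        n_drop = min(n_drop, len(surviving) - min_features)
        drop = order[:n_drop]
        eliminated.extend(drop)
        surviving = [c for c in surviving if c not in drop]
        it += 1
    # rank the survivors by a final importance fit
    if len(surviving) > 1:
        order = _importance_order(X[surviving], y, seed + it)
        surviving = order[::-1]
    return surviving + eliminated[::-1]


def rf_rfe(
    X: pd.DataFrame,
    y: pd.Series,
    threshold: int,
    seed: int = 0,
) -> list[str]:
    """Select exactly ``threshold`` features by recursive RF elimination."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if threshold > X.shape[1]:
        raise ValueError(f"threshold {threshold} exceeds {X.shape[1]} features")
    if threshold == X.shape[1]:
        return list(X.columns)
    path = rfe_path(X, y, seed=seed, min_features=threshold)
    return sorted(path[:threshold], key=list(X.columns).index)


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

MODEL_FAMILIES = ("logistic", "cart", "random_forest")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "cart": {"max_depth": [2, 3, 4, 5, 6, 7, 8], "min_samples_leaf": [5, 10, 20]},
    "random_forest": {"n_estimators": [200, 500], "max_depth": [None, 4, 8]},
}


def fit_model(
    X: pd.DataFrame,
    y: pd.Series,
    model: str,
    params: Mapping | None = None,
    seed: int = 0,
):
    """Fit one of the three model families; deterministic under ``seed``.

    Logistic regression is fit on z-scored features (scaler fit on the given
    training data); the tree families consume raw features.
    """
    if y.nunique() < 2:
        raise ValueError("training labels are single-class")
    params = dict(params or {})
    if model == "logistic":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed, **params)),
        ])
    elif model == "cart":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif model == "random_forest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        raise ValueError(f"unknown model family {model!r}")
    est.fit(X.to_numpy(), y.to_numpy(dtype=int))
    est.feature_names_ = list(X.columns)
    return est


def predict_proba(model, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Probability of the positive (case) class."""
    arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    return model.predict_proba(arr)[:, 1]


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLConfig:
    model: str = "random_forest"
    outer_folds: int = 5
    inner_folds: int = 3
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    rfe_thresholds: tuple[int, ...] = (20, 35, 50)
    grid: Mapping[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model!r}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")

    def param_grid(self) -> list[dict]:
        grid = dict(self.grid if self.grid is not None else DEFAULT_GRIDS[self.model])
        combos = [{}]
        for key, values in grid.items():
            combos = [{**c, key: v} for c in combos for v in values]
        return combos


@dataclass
class CVResult:
    model: str
    fold_metrics: list[MetricSet]
    selected_features: list[list[str]]
    chosen_params: list[dict]
    chosen_thresholds: list[int]
    test_index_sets: list[list[str]] = field(default_factory=list)
    n_synthetic_per_fold: list[int] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.fold_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals))

    def sd(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.fold_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"model": self.model}  # type: ignore[dict-item]
        for metric in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1", "auc"):
            out[f"{metric}_mean"] = self.mean(metric)
            out[f"{metric}_sd"] = self.sd(metric)
        return out


def _score_fold(model, X_test: pd.DataFrame, y_test: pd.Series) -> MetricSet:
    scores = predict_proba(model, X_test)
    pred = scores >= 0.5
    y_arr = y_test.to_numpy(dtype=bool)
    cm = ConfusionMatrix(
        tp=int((pred & y_arr).sum()),
        fp=int((pred & ~y_arr).sum()),
        tn=int((~pred & ~y_arr).sum()),
        fn=int((~pred & y_arr).sum()),
    )
    base = _metrics(cm)
    f1_val = None
    if base.ppv is not None and base.sensitivity is not None and base.ppv + base.sensitivity > 0:
        f1_val = _f1(base.ppv, base.sensitivity)
    auc_val = None
    if y_arr.any() and not y_arr.all():
        auc_val = _auc_map(
            {str(i): s for i, s in zip(y_test.index, scores)},
            {str(i): bool(v) for i, v in zip(y_test.index, y_arr)},
        )
    return MetricSet(
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        ppv=base.ppv,
        npv=base.npv,
        accuracy=base.accuracy,
        f1=f1_val,
        auc=auc_val,
    )


def nested_cv(features: FeatureMatrix, config: MLConfig) -> CVResult:
    """Nested stratified cross-validation with SMOTE and RF-RFE.

    Outer loop estimates generalization; for each outer training set, the
    inner loop rebalances inner-training folds with SMOTE (validation folds
    are never resampled), computes an RF elimination path per inner-training
    fold, and grid-searches hyperparameters x elimination thresholds by mean
    inner-validation AUC. The winning configuration is refit on the SMOTE'd
    outer-training set and scored once on the untouched outer test fold.
    """
    X, y = features.X, features.y
    thresholds = tuple(t for t in config.rfe_thresholds if t <= X.shape[1])
    if not thresholds:
        thresholds = (X.shape[1],)
    outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=config.seed)
    result = CVResult(config.model, [], [], [], [])

    y_int = y.to_numpy(dtype=int)
    for fold, (tr_idx, te_idx) in enumerate(outer.split(X, y_int)):
        X_tr, y_tr = X.iloc[tr_idx], y.iloc[tr_idx]
        X_te, y_te = X.iloc[te_idx], y.iloc[te_idx]
        if y_tr.nunique() < 2 or y_te.nunique() < 2:
            raise ValueError("fold too small for stratification: single-class fold")

        inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=config.seed + 100 + fold)
        combos = config.param_grid()
        scores = np.zeros((len(thresholds), len(combos)))
        for in_fold, (in_tr, in_va) in enumerate(inner.split(X_tr, y_tr.to_numpy(dtype=int))):
            X_in, y_in = X_tr.iloc[in_tr], y_tr.iloc[in_tr]
            X_va, y_va = X_tr.iloc[in_va], y_tr.iloc[in_va]
            X_bal, y_bal, _ = smote(
                X_in, y_in, k=config.smote_k,
                target_ratio=config.smote_target_ratio,
                seed=config.seed + 1000 + 10 * fold + in_fold,
            )
            path = rfe_path(X_bal, y_bal, seed=config.seed + 31 * fold + in_fold,
                            min_features=min(thresholds))
            for ti, thr in enumerate(thresholds):
                cols = path[:thr]
                for ci, params in enumerate(combos):
                    model = fit_model(X_bal[cols], y_bal, config.model, params,
                                      seed=config.seed + fold)
                    s = predict_proba(model, X_va[cols])
                    ranks = pd.Series(s).rank().to_numpy()
                    yv = y_va.to_numpy(dtype=bool)
                    n_pos, n_neg = int(yv.sum()), int((~yv).sum())
                    auc_v = (
                        (ranks[yv].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
                        if n_pos and n_neg else 0.5
                    )
                    scores[ti, ci] += auc_v
        best_ti, best_ci = np.unravel_index(int(np.argmax(scores)), scores.shape)
        best_thr, best_params = thresholds[best_ti], combos[best_ci]

        X_bal, y_bal, syn_mask = smote(
            X_tr, y_tr, k=config.smote_k,
            target_ratio=config.smote_target_ratio,
            seed=config.seed + 2000 + fold,
        )
        path = rfe_path(X_bal, y_bal, seed=config.seed + 500 + fold, min_features=min(thresholds))
        cols = path[:best_thr]
        model = fit_model(X_bal[cols], y_bal, config.model, best_params, seed=config.seed + fold)
        result.fold_metrics.append(_score_fold(model, X_te[cols], y_te))
        result.selected_features.append(list(cols))
        result.chosen_params.append(dict(best_params))
        result.chosen_thresholds.append(int(best_thr))
        result.test_index_sets.append([str(i) for i in X_te.index])
        result.n_synthetic_per_fold.append(int(syn_mask.sum()))
    return result


# ---------------------------------------------------------------------------
# Monte-Carlo permutation Shapley attributions
# ---------------------------------------------------------------------------


@dataclass
class ShapReport:
    """Per-sample signed attributions and their mean absolute summary."""

    attributions: pd.DataFrame  # rows = samples, columns = features
    baseline: float  # mean model output over the sampled background rows
    predictions: np.ndarray  # model output per explained sample

    def mean_abs(self) -> pd.Series:
        return self.attributions.abs().mean(axis=0).sort_values(ascending=False)

    def local_accuracy_residuals(self) -> np.ndarray:
        return self.attributions.sum(axis=1).to_numpy() - (self.predictions - self.baseline)


def mean_abs_shap(
    score_fn: Callable[[np.ndarray], np.ndarray],
    X: pd.DataFrame,
    background: pd.DataFrame,
    mc_samples: int = 128,
    seed: int = 0,
) -> ShapReport:
    """Monte-Carlo permutation estimate of Shapley attributions.

    For each draw, one background row and one feature permutation are
    sampled; features are switched from the background value to the
    explained sample's value in permutation order and the marginal change in
    model output is credited to the switched feature. Attributions for a
    sample sum exactly to ``score(sample) - mean(score(background draws))``.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    if background.empty:
        raise ValueError("background sample must be non-empty")
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    Bv = background.to_numpy(dtype=float)
    n, F = Xv.shape
    phi = np.zeros((n, F))
    base_scores = np.zeros(mc_samples)

    for draw in range(mc_samples):
        b = Bv[rng.integers(0, len(Bv))]
        perm = rng.permutation(F)
        # hybrids: row j of `states` has the first j permuted features from x
        states = np.empty((F + 1, n, F))
        states[0] = np.broadcast_to(b, (n, F))
        current = np.broadcast_to(b, (n, F)).copy()
        for j, feat in enumerate(perm, start=1):
            current = current.copy()
            current[:, feat] = Xv[:, feat]
            states[j] = current
        preds = score_fn(states.reshape((F + 1) * n, F)).reshape(F + 1, n)
        base_scores[draw] = preds[0, 0]
        for j, feat in enumerate(perm, start=1):
            phi[:, feat] += preds[j] - preds[j - 1]

    phi /= mc_samples
    baseline = float(base_scores.mean())
    return ShapReport(
        attributions=pd.DataFrame(phi, index=X.index, columns=X.columns),
        baseline=baseline,
        predictions=score_fn(Xv),
    )
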
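"""Nested cross-validation engine for treatment-response prediction.

Performance of a gene + clinical classifier is estimated by repeated
nested cross-validation: the outer loop measures generalisation on
left-out folds, while *all* adaptive steps — gene filtering and
hyperparameter tuning — run strictly inside the outer-training data
(tuning by inner cross-validation on log loss for binary outcomes, or R^2
for the ordinal disease-activity regression). Predictions from the outer
test folds of one repeat are pooled before computing ROC AUC, accuracy
and balanced accuracy, so each sample is predicted exactly once per
repeat and no metric ever touches a training prediction.

Clinical covariates bypass the gene filter and are always offered to the
learner.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .learners import (
    ElasticNetLinear,
    ElasticNetLogit,
    GradientBoostedTrees,
    OrdinalRidge,
    make_learner,
)

__all__ = [
    "FoldPlan",
    "FilterSpec",
    "ModelSpec",
    "NestedCVResult",
    "FittedResponseModel",
    "make_fold_plan",
    "ttest_filter",
    "sparse_embedded_filter",
    "tune_inner",
    "nested_cv",
    "ordinal_encode_outcome",
    "ordinal_to_binary",
    "evaluate",
    "aggregate_importance",
    "fit_final",
    "external_validate",
]

ORDINAL_LEVELS = ("remission", "low", "moderate", "high")


# ---------------------------------------------------------------- fold plans


@dataclass
class FoldPlan:
    """Repeated nested fold assignments.

    ``outer[r]`` is a length-n array of outer fold ids (0..outer_k-1) for
    repeat ``r``; ``inner[(r, f)]`` is a length-n array of inner fold ids
    over the training samples of outer fold ``f`` (-1 marks the samples of
    the outer test fold).
    """

    repeats: int
    outer_k: int
    inner_k: int
    stratified: bool
    seed: int
    outer: list[np.ndarray] = field(default_factory=list)
    inner: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.outer[0])


def _fold_labels(y: np.ndarray, k: int, stratified: bool, rng) -> np.ndarray:
    n = len(y)
    labels = np.full(n, -1, dtype=int)
    if stratified:
        start = 0
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            perm = rng.permutation(members)
            # rotate the fold offset across classes so overall sizes balance
            labels[perm] = (np.arange(len(perm)) + start) % k
            start += len(perm)
    else:
        perm = rng.permutation(n)
        labels[perm] = np.arange(n) % k
    return labels


def make_fold_plan(
    labels,
    outer_k: int = 10,
    inner_k: int = 10,
    repeats: int = 25,
    stratified: bool = True,
    seed: int = 0,
) -> FoldPlan:
    """Build a repeated nested cross-validation fold plan.

    Outer folds partition all samples per repeat; inner folds partition
    exactly the training samples of each outer fold. Stratification keeps
    per-fold class counts within one sample of proportionality.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < outer_k:
        raise ValueError(f"n={n} smaller than outer_k={outer_k}")
    if stratified:
        counts = pd.Series(y).value_counts()
        if counts.min() < outer_k:
            raise ValueError(
                f"minority class has {counts.min()} samples < outer_k={outer_k}; "
                "use fewer folds or stratified=False"
            )
    rng = np.random.default_rng(seed)
    plan = FoldPlan(repeats, outer_k, inner_k, stratified, seed)
    for r in range(repeats):
        outer = _fold_labels(y, outer_k, stratified, rng)
        plan.outer.append(outer)
        for f in range(outer_k):
            train = np.flatnonzero(outer != f)
            inner = np.full(n, -1, dtype=int)
            inner[train] = _fold_labels(y[train], inner_k, stratified, rng)
            plan.inner[(r, f)] = inner
    return plan


# ------------------------------------------------------------------ filters


@dataclass
class FilterSpec:
    """In-fold gene feature selection.

    ``ttest_top_n`` keeps the ``n_keep`` genes with the smallest two-sided
    Welch t p-values; ``sparse_embedded`` keeps genes with nonzero
    coefficients in an L1/L2-penalised fit at the grid point whose
    retained count falls inside ``size_bounds``.
    """

    method: str = "ttest_top_n"
    n_keep: int = 30
    penalty_grid: tuple = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01)
    size_bounds: tuple[int, int] = (25, 40)
    l1_ratio: float = 1.0

    def __post_init__(self):
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        if self.method not in ("ttest_top_n", "sparse_embedded"):
            raise ValueError(f"unknown filter method {self.method!r}")


def ttest_filter(X: pd.DataFrame, y, n_keep: int) -> list[str]:
    """Top-``n_keep`` features by ascending two-tailed Welch t p-value.

    Ties are broken by larger absolute t statistic, then feature name.
    """
    y = np.asarray(y)
    if n_keep > X.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds {X.shape[1]} features")
    g1 = X.to_numpy(dtype=float)[np.asarray(y, dtype=float) >= 0.5]
    g0 = X.to_numpy(dtype=float)[np.asarray(y, dtype=float) < 0.5]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both classes need >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    order = sorted(
        range(X.shape[1]), key=lambda j: (p[j], -abs(t[j]), str(X.columns[j]))
    )
    return [X.columns[j] for j in order[:n_keep]]


def sparse_embedded_filter(
    X: pd.DataFrame,
    y,
    spec: FilterSpec,
    ordinal: bool = False,
) -> list[str]:
    """Embedded selection: genes retained by a sparse penalised model.

    Scans the penalty grid (strong to weak) and returns the retained set
    at the grid point whose nonzero count falls inside
    ``spec.size_bounds``; if no point lands inside, the closest count from
    below is used. If every grid point retains nothing, falls back to the
    t-test filter with a warning.
    """
    lo, hi = spec.size_bounds
    best: list[str] | None = None
    best_count = -1
    for alpha in sorted(spec.penalty_grid, reverse=True):
        if ordinal:
            model = ElasticNetLinear(alpha=alpha, l1_ratio=spec.l1_ratio)
        else:
            model = ElasticNetLogit(alpha=alpha, l1_ratio=spec.l1_ratio)
        model.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
        nz = np.flatnonzero(model.coef_)
        count = len(nz)
        if lo <= count <= hi:
            return [X.columns[j] for j in nz]
        if count < lo and count > best_count:
            best, best_count = [X.columns[j] for j in nz], count
    if not best:
        warnings.warn("sparse filter retained nothing; falling back to t-test filter")
        return ttest_filter(X, y, min(spec.n_keep, X.shape[1]))
    return best


# ------------------------------------------------------------------- tuning


@dataclass
class ModelSpec:
    """Learner choice, hyperparameter grid and outcome mode.

    ``grid`` is an ordered list of parameter dicts, simplest model first
    (used for tie-breaking). ``metric`` must be ``log_loss`` for binary
    outcomes and ``r_squared`` for the ordinal regression mode.
    """

    learner: str = "elastic_net"
    grid: tuple = ({"alpha": 0.5}, {"alpha": 0.1}, {"alpha": 0.02})
    outcome: str = "binary"
    metric: str = "log_loss"
    tau: float = 0.5

    def __post_init__(self):
        if self.outcome not in ("binary", "ordinal4"):
            raise ValueError("outcome must be 'binary' or 'ordinal4'")
        if self.metric not in ("log_loss", "r_squared"):
            raise ValueError("metric must be 'log_loss' or 'r_squared'")
        if self.metric == "r_squared" and self.outcome != "ordinal4":
            raise ValueError("r_squared tuning is only for the ordinal mode")
        if self.outcome == "ordinal4" and self.metric == "log_loss":
            raise ValueError("ordinal mode tunes on r_squared")
        if not self.grid:
            raise ValueError("empty hyperparameter grid")


def _log_loss(y, p) -> float:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _r_squared(y, pred) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def tune_inner(
    model_spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    inner_labels: np.ndarray,
) -> dict:
    """Pick the grid point with the best mean inner-fold score.

    Binary mode minimises log loss; ordinal mode maximises R^2. Exact ties
    go to the earliest (simplest) grid point. A learner failure on any
    fold scores that grid point worst.
    """
    folds = np.unique(inner_labels[inner_labels >= 0])
    best_params, best_score = None, None
    sign = 1.0 if model_spec.metric == "log_loss" else -1.0  # minimise signed score
    for params in model_spec.grid:
        scores = []
        failed = False
        for f in folds:
            tr = inner_labels >= 0
            tr_f = tr & (inner_labels != f)
            va_f = inner_labels == f
            try:
                learner = make_learner(model_spec.learner, **params)
                learner.fit(X[tr_f], y[tr_f])
                if model_spec.outcome == "binary":
                    p = learner.predict_proba(X[va_f])[:, 1]
                    scores.append(_log_loss(y[va_f], p))
                else:
                    pred = learner.predict(X[va_f])
                    scores.append(-_r_squared(y[va_f], pred))
            except Exception as exc:  # noqa: BLE001 - scored worst, logged
                warnings.warn(f"learner failed on inner fold {f}: {exc}")
                failed = True
                break
        score = np.inf if failed else float(np.mean(scores))
        if best_score is None or score < best_score - 1e-12:
            best_params, best_score = dict(params), score
    return best_params


# ------------------------------------------------------------ outcome codes


def ordinal_encode_outcome(das28) -> tuple[np.ndarray, np.ndarray]:
    """Encode DAS28-ESR into 4 disease-activity levels and numeric codes.

    remission < 2.6; low [2.6, 3.2); moderate [3.2, 5.1]; high > 5.1.
    Binary response corresponds to code <= 1 (DAS28-ESR < 3.2).
    """
    x = np.asarray(das28, dtype=float)
    if (x < 0).any():
        raise ValueError("DAS28 values must be non-negative")
    codes = np.select(
        [x < 2.6, x < 3.2, x <= 5.1], [0, 1, 2], default=3
    )
    levels = np.array(ORDINAL_LEVELS)[codes]
    return levels, codes.astype(int)


def ordinal_to_binary(predictions, tau: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Convert real-valued ordinal-code predictions to a response score.

    The score is ``sigmoid((1.5 - prediction) / tau)`` — monotone
    decreasing in the predicted code, exactly 0.5 at the low/moderate
    midpoint 1.5 — and the label is responder iff the prediction is below
    1.5. AUC is invariant to ``tau``.
    """
    pred = np.asarray(predictions, dtype=float)
    if not np.isfinite(pred).all():
        raise ValueError("predictions must be finite")
    score = expit((1.5 - pred) / tau)
    return score, (pred < 1.5).astype(int)


# --------------------------------------------------------------- evaluation


def evaluate(scores, truth, threshold: float = 0.5) -> dict:
    """ROC AUC (Mann-Whitney with half-credit ties), accuracy, balanced
    accuracy and the confusion matrix at the given score threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        auc = np.nan
    else:
        r = stats.rankdata(s)
        auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / n1 if n1 else np.nan
    spec = tn / n0 if n0 else np.nan
    bacc = np.nanmean([sens, spec])
    return {
        "auc": float(auc),
        "accuracy": float(acc),
        "balanced_accuracy": float(bacc),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


# ---------------------------------------------------------------- nested CV


@dataclass
class NestedCVResult:
    """Pooled outer-fold predictions, per-repeat metrics and per-fold
    selections/importances from a nested CV run."""

    predictions: pd.DataFrame  # repeat, sample, fold, score, truth [, raw]
    metrics: pd.DataFrame  # per repeat
    fold_records: list[dict]
    model_spec: ModelSpec
    filter_spec: FilterSpec

    def summary(self) -> dict:
        out = {c: float(self.metrics[c].mean()) for c in self.metrics.columns}
        out.update({f"{c}_sd": float(self.metrics[c].std(ddof=1)) for c in self.metrics.columns})
        return out


def _select_features(
    X: pd.DataFrame, y, filter_spec: FilterSpec, ordinal: bool
) -> list[str]:
    if filter_spec.method == "ttest_top_n":
        yb = np.asarray(y) <= 1 if ordinal else np.asarray(y)
        return ttest_filter(X, np.asarray(yb, dtype=float), min(filter_spec.n_keep, X.shape[1]))
    return sparse_embedded_filter(X, y, filter_spec, ordinal=ordinal)


def nested_cv(
    X: pd.DataFrame,
    y,
    clinical: pd.DataFrame | None,
    filter_spec: FilterSpec,
    model_spec: ModelSpec,
    plan: FoldPlan,
    leaky: bool = False,
) -> NestedCVResult:
    """Run the full nested cross-validation procedure.

    ``X`` is samples x genes (VST scale), ``clinical`` samples x already
    transformed covariates (always passed to the learner, never filtered).
    ``y`` is the binary response, or ordinal codes 0-3 in ordinal mode.

    The ``leaky`` flag performs feature selection on the *full* data before
    the folds. It exists solely as a test harness to demonstrate the
    selection bias that nested CV removes; never use it for reporting.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n or (clinical is not None and clinical.shape[0] != n):
        raise ValueError("X, y and clinical must align on samples")
    ordinal = model_spec.outcome == "ordinal4"
    clin_cols = list(clinical.columns) if clinical is not None else []
    leaky_features = _select_features(X, y, filter_spec, ordinal) if leaky else None

    records: list[dict] = []
    pred_rows = []
    metric_rows = []
    for r in range(plan.repeats):
        outer = plan.outer[r]
        pooled_score = np.full(n, np.nan)
        pooled_raw = np.full(n, np.nan)
        for f in range(plan.outer_k):
            tr = outer != f
            te = outer == f
            feats = leaky_features if leaky else _select_features(
                X.iloc[tr], y[tr], filter_spec, ordinal
            )
            cols = list(feats) + clin_cols
            Xf = X[feats]
            if clinical is not None:
                Xf = pd.concat([Xf, clinical], axis=1)
            mat = Xf.to_numpy(dtype=float)
            inner = plan.inner[(r, f)]
            best = tune_inner(model_spec, mat, y, inner)
            learner = make_learner(model_spec.learner, **best)
            learner.fit(mat[tr], y[tr])
            if ordinal:
                raw = learner.predict(mat[te])
                score, _ = ordinal_to_binary(raw, model_spec.tau)
                pooled_raw[te] = raw
            else:
                score = learner.predict_proba(mat[te])[:, 1]
            pooled_score[te] = score
            records.append(
                {
                    "repeat": r,
                    "fold": f,
                    "selected": list(feats),
                    "params": best,
                    "importance": dict(zip(cols, np.asarray(learner.importance_, dtype=float))),
                }
            )
        assert not np.isnan(pooled_score).any(), "outer folds failed to cover all samples"
        yb = (y <= 1).astype(float) if ordinal else y
        m = evaluate(pooled_score, yb)
        row = {
            "repeat": r,
            "auc": m["auc"],
            "accuracy": m["accuracy"],
            "balanced_accuracy": m["balanced_accuracy"],
        }
        if ordinal:
            row["r_squared"] = _r_squared(y, pooled_raw)
        metric_rows.append(row)
        for i in range(n):
            pred_rows.append(
                {
                    "repeat": r,
                    "sample": X.index[i],
                    "fold": int(outer[i]),
                    "score": pooled_score[i],
                    "truth": yb[i],
                }
            )
    return NestedCVResult(
        predictions=pd.DataFrame(pred_rows),
        metrics=pd.DataFrame(metric_rows).set_index("repeat"),
        fold_records=records,
        model_spec=model_spec,
        filter_spec=filter_spec,
    )


def aggregate_importance(
    fold_records: list[dict],
    final_importance: dict | None = None,
    direction: dict | None = None,
) -> pd.DataFrame:
    """Variable-importance stability across outer CV folds.

    Per predictor: mean and standard error of its importance over the
    folds where it was selected, selection frequency, optional direction of
    association with response, and the final-model importance if given.
    """
    if not fold_records:
        raise ValueError("no fold records")
    total = len(fold_records)
    values: dict[str, list[float]] = {}
    for rec in fold_records:
        for feat, imp in rec["importance"].items():
            values.setdefault(feat, []).append(float(imp))
    rows = []
    for feat, v in values.items():
        v = np.asarray(v)
        rows.append(
            {
                "predictor": feat,
                "mean_importance": float(v.mean()),
                "se_importance": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                "frequency": len(v) / total,
                "direction": int(np.sign(direction.get(feat, 0))) if direction else 0,
                "final_importance": float(final_importance.get(feat, np.nan))
                if final_importance
                else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("predictor")
    return out.sort_values(["frequency", "mean_importance"], ascending=False)


# -------------------------------------------------------------- final model


@dataclass
class FittedResponseModel:
    """A finalised, serialisable response model for one drug.

    The payload stores everything needed to reproduce predictions without
    refitting (coefficients or trees plus the feature scaling contract).
    Expression inputs must be on the VST scale (pseudo-RNA-Seq from the
    hybridisation-count bridge qualifies); clinical covariates must be the
    transformed set (sqTJC, sqSJC, sqESR, logCRP, ...).
    """

    drug: str
    outcome: str  # e.g. "DAS28-ESR<3.2"
    predictors: list[str]
    gene_predictors: list[str]
    clinical_predictors: list[str]
    learner: str
    params: dict
    payload: dict
    preprocessing: dict
    version: str = "1"

    # -- prediction from the serialised payload only (round-trip safe) --
    def _scores(self, mat: np.ndarray) -> np.ndarray:
        pl = self.payload
        if self.learner in ("elastic_net",):
            xs = (mat - np.asarray(pl["x_mean"])) / np.asarray(pl["x_sd"])
            return expit(pl["intercept"] + xs @ np.asarray(pl["coef"]))
        if self.learner == "ordinal_linear":
            xs = (mat - np.asarray(pl["x_mean"])) / np.asarray(pl["x_sd"])
            codes = pl["y_mean"] + xs @ np.asarray(pl["coef"])
            score, _ = ordinal_to_binary(codes, pl.get("tau", 0.5))
            return score
        if self.learner == "gradient_boosted_trees":
            F = np.full(mat.shape[0], pl["init"])
            for tr in pl["trees"]:
                F = F + pl["learning_rate"] * _tree_apply(tr, mat)
            return expit(F)
        raise ValueError(f"cannot score serialised learner {self.learner!r}")

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """Response probability per sample; ``features`` must contain every
        predictor column (genes on VST scale + transformed clinical)."""
        missing = [c for c in self.predictors if c not in features.columns]
        if missing:
            raise KeyError(f"missing predictor(s) for {self.drug} model: {missing}")
        mat = features[self.predictors].to_numpy(dtype=float)
        return pd.Series(self._scores(mat), index=features.index, name=f"p_{self.drug}")

    def to_json(self, path=None) -> str:
        obj = {
            "drug": self.drug,
            "outcome": self.outcome,
            "predictors": self.predictors,
            "gene_predictors": self.gene_predictors,
            "clinical_predictors": self.clinical_predictors,
            "learner": self.learner,
            "params": self.params,
            "payload": self.payload,
            "preprocessing": self.preprocessing,
            "version": self.version,
        }
        text = json.dumps(obj, indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedResponseModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        obj = json.loads(text)
        return cls(**obj)


def _jsonify(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")


def _tree_apply(tree_payload: dict, X: np.ndarray) -> np.ndarray:
    cl = np.asarray(tree_payload["children_left"])
    cr = np.asarray(tree_payload["children_right"])
    feat = np.asarray(tree_payload["feature"])
    thr = np.asarray(tree_payload["threshold"])
    val = np.asarray(tree_payload["value"])
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        node = 0
        while cl[node] != -1:
            node = cl[node] if row[feat[node]] <= thr[node] else cr[node]
        out[i] = val[node]
    return out


def _serialise_learner(learner, model_spec: ModelSpec) -> dict:
    if isinstance(learner, ElasticNetLogit):
        return {
            "x_mean": learner.x_mean_,
            "x_sd": learner.x_sd_,
            "coef": learner.coef_,
            "intercept": learner.intercept_,
        }
    if isinstance(learner, OrdinalRidge):
        return {
            "x_mean": learner.x_mean_,
            "x_sd": learner.x_sd_,
            "coef": learner.coef_,
            "y_mean": learner.y_mean_,
            "tau": model_spec.tau,
        }
    if isinstance(learner, GradientBoostedTrees):
        trees = []
        for tree, values in learner.trees_:
            t = tree.tree_
            trees.append(
                {
                    "children_left": t.children_left,
                    "children_right": t.children_right,
                    "feature": t.feature,
                    "threshold": t.threshold,
                    "value": values,
                }
            )
        return {
            "init": learner.init_,
            "learning_rate": learner.learning_rate,
            "trees": trees,
        }
    raise ValueError(f"no serialiser for {type(learner).__name__}")


def fit_final(
    X: pd.DataFrame,
    y,
    clinical: pd.DataFrame | None,
    filter_spec: FilterSpec,
    model_spec: ModelSpec,
    inner_k: int = 10,
    seed: int = 0,
    drug: str = "",
) -> FittedResponseModel:
    """Fit the deployable model on the whole cohort.

    Feature selection on the full data, a final round of CV tuning on the
    full data, then a single fit. The artifact records predictors, fitted
    parameters and the preprocessing contract.
    """
    y = np.asarray(y, dtype=float)
    ordinal = model_spec.outcome == "ordinal4"
    feats = _select_features(X, y, filter_spec, ordinal)
    clin_cols = list(clinical.columns) if clinical is not None else []
    Xf = pd.concat([X[feats], clinical], axis=1) if clinical is not None else X[feats]
    mat = Xf.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    strat = (y <= 1).astype(int) if ordinal else y
    folds = _fold_labels(strat, min(inner_k, len(y)), True, rng)
    best = tune_inner(model_spec, mat, y, folds)
    learner = make_learner(model_spec.learner, **best)
    learner.fit(mat, y)
    payload = _serialise_learner(learner, model_spec)
    return FittedResponseModel(
        drug=drug,
        outcome="DAS28-ESR<3.2",
        predictors=list(Xf.columns),
        gene_predictors=list(feats),
        clinical_predictors=clin_cols,
        learner=model_spec.learner,
        params=best,
        payload={k: _to_plain(v) for k, v in payload.items()},
        preprocessing={
            "expression_scale": "VST",
            "clinical_transforms": "sqrt(TJC,SJC,ESR), log(CRP+offset)",
            "feature_mean": list(np.asarray(mat.mean(axis=0), dtype=float)),
            "feature_sd": list(np.asarray(mat.std(axis=0), dtype=float)),
        },
    )


def _to_plain(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, list):
        return [_to_plain(x) for x in v]
    if isinstance(v, dict):
        return {k: _to_plain(x) for k, x in v.items()}
    if isinstance(v, (np.integer, np.floating)):
        return float(v)
    return v


def external_validate(
    model: FittedResponseModel,
    X_new: pd.DataFrame,
    clinical_new: pd.DataFrame | None,
    y_new,
) -> dict:
    """Score a finalised model on an external (batch-adjusted) cohort.

    Raises if any model predictor is absent; warns when the new cohort's
    feature means drift more than 3 training sds from the training means
    (scale mismatch check). Returns :func:`evaluate` metrics.
    """
    feats = pd.concat([X_new, clinical_new], axis=1) if clinical_new is not None else X_new
    missing = [c for c in model.predictors if c not in feats.columns]
    if missing:
        raise KeyError(f"validation cohort missing predictor(s): {missing}")
    mat = feats[model.predictors].to_numpy(dtype=float)
    mu_train = np.asarray(model.preprocessing["feature_mean"])
    sd_train = np.asarray(model.preprocessing["feature_sd"])
    drift = np.abs(mat.mean(axis=0) - mu_train) > 3 * np.maximum(sd_train, 1e-12)
    if drift.any():
        bad = [model.predictors[j] for j in np.flatnonzero(drift)]
        warnings.warn(f"possible scale mismatch for predictors: {bad[:10]}")
    scores = model.predict_proba(feats)
    return evaluate(scores.to_numpy(), np.asarray(y_new, dtype=float))
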
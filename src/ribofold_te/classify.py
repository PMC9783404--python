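"""High/low-TE classification over repeated random splits.

Protocol: the labeled feature table is split into 70% train / 30% test
100 times (stratified); within each split a grid of hyper-parameters is
tuned by stratified ten-fold cross-validation maximizing mean AUC, the
winning parameters are refit on the whole training partition, and test
AUC is recorded. Two model families are supported: a random forest
("rf", the importance-bearing model) and an elastic-net penalized
logistic regression ("en"). Missing features are imputed with training-
partition medians inside each split; features are z-scored (from the
training partition) for the elastic net only, so no test-set information
leaks into fitting.

Feature importances are the forest's impurity-based (mean decrease in
impurity) importances, normalized to sum to 1 per split, and are
aggregated two ways: summed within the four feature groups (sequence /
vivo / vitro / insilico) per split, and averaged across splits per
meta-gene bin for the vivo and vitro bin features.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger("ribofold_te")

N_SPLITS = 100
TRAIN_FRAC = 0.7
CV_FOLDS = 10

DEFAULT_RF_GRID: dict[str, list] = {
    "n_estimators": [100, 500],
    "max_features": ["sqrt", 1 / 3],
    "min_samples_leaf": [1, 5],
}
DEFAULT_EN_GRID: dict[str, list] = {
    "l1_ratio": [0.1, 0.5, 0.9],
    "C": list(np.logspace(-3, 2, 10)),
}

_BIN_RE = re.compile(r"^(vivo|vitro)_bin_(\d+)$")


@dataclass
class SplitResult:
    split_index: int
    seed: int
    tuned_params: dict
    auc_rf: float = math.nan
    auc_en: float = math.nan
    importances: pd.Series | None = None


@dataclass
class ImportanceSummary:
    """Grouped and per-bin importance aggregates across splits."""

    group_sums: pd.DataFrame  # splits x groups, rows sum to 1
    bin_means: pd.DataFrame  # bins x {vivo, vitro}, mean importance over splits


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def make_splits(
    labels: Sequence[int],
    n_splits: int = N_SPLITS,
    train_frac: float = TRAIN_FRAC,
    base_seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random 70/30 splits; split i is drawn with seed base_seed+i.

    |train| = round(train_frac * n); train and test are disjoint and
    exhaustive, and each class appears in both partitions (resampled
    within the split's seed if a class would vanish, which stratification
    makes all but impossible).
    """
    y = np.asarray(labels)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train_target = round(train_frac * n)
    classes = np.unique(y)
    splits = []
    for i in range(n_splits):
        rng = np.random.default_rng((base_seed + i) % 2**31)
        for attempt in range(100):
            train_parts, test_parts = [], []
            # proportional allocation with largest-remainder rounding
            quotas = {c: train_frac * np.sum(y == c) for c in classes}
            k = {c: int(quotas[c]) for c in classes}
            short = n_train_target - sum(k.values())
            order = sorted(classes, key=lambda c: quotas[c] - k[c], reverse=True)
            for c in order[:short]:
                k[c] += 1
            for c in classes:
                idx = np.flatnonzero(y == c)
                perm = rng.permutation(idx)
                train_parts.append(perm[: k[c]])
                test_parts.append(perm[k[c] :])
            train = np.sort(np.concatenate(train_parts))
            test = np.sort(np.concatenate(test_parts))
            if all(np.any(y[train] == c) and np.any(y[test] == c) for c in classes):
                break
            logger.warning("split %d attempt %d lost a class; resampling", i, attempt)
        splits.append((train, test))
    return splits


def _build_pipeline(model: str, params: Mapping, seed: int) -> Pipeline:
    if model == "rf":
        est = RandomForestClassifier(random_state=seed % 2**31, n_jobs=1, **params)
        steps = [("impute", SimpleImputer(strategy="median")), ("model", est)]
    elif model == "en":
        est = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            max_iter=5000,
            tol=1e-4,
            random_state=seed % 2**31,
            **params,
        )
        steps = [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("model", est),
        ]
    else:
        raise ValueError(f"unknown model {model!r}")
    return Pipeline(steps)


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune_and_train(
    X: pd.DataFrame,
    y: Sequence[int],
    model: str = "rf",
    cv_folds: int = CV_FOLDS,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
):
    """Grid search by stratified CV on mean AUC, then refit on all of X.

    Ties in mean CV AUC are broken by grid order. A single-point grid
    skips the search entirely. Returns (fitted pipeline, tuned params).
    """
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if grid is None:
        grid = DEFAULT_RF_GRID if model == "rf" else DEFAULT_EN_GRID
    points = _grid_points(grid)
    if len(points) == 1:
        best = points[0]
    else:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % 2**31)
        folds = list(cv.split(X, y))
        best, best_auc = None, -np.inf
        for params in points:
            aucs = []
            for tr, va in folds:
                pipe = _build_pipeline(model, params, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pipe.fit(X.iloc[tr], y[tr])
                scores = pipe.predict_proba(X.iloc[va])[:, 1]
                aucs.append(evaluate_auc(scores, y[va]))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:  # strict: ties keep earlier grid point
                best, best_auc = params, mean_auc
    pipe = _build_pipeline(model, best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X, y)
    return pipe, dict(best)


def run_splits(
    X: pd.DataFrame,
    y: Sequence[int],
    n_splits: int = N_SPLITS,
    train_frac: float = TRAIN_FRAC,
    cv_folds: int = CV_FOLDS,
    base_seed: int = 0,
    rf_grid: Mapping[str, Sequence] | None = None,
    en_grid: Mapping[str, Sequence] | None = None,
    models: Sequence[str] = ("rf", "en"),
) -> list[SplitResult]:
    """The full repeated-split protocol; one SplitResult per split."""
    y = np.asarray(y)
    splits = make_splits(y, n_splits=n_splits, train_frac=train_frac, base_seed=base_seed)
    results: list[SplitResult] = []
    for i, (train, test) in enumerate(splits):
        seed = (base_seed + i) % 2**31
        res = SplitResult(split_index=i, seed=seed, tuned_params={})
        Xtr, Xte = X.iloc[train], X.iloc[test]
        ytr, yte = y[train], y[test]
        if "rf" in models:
            pipe, params = tune_and_train(Xtr, ytr, "rf", cv_folds, rf_grid, seed)
            res.auc_rf = evaluate_auc(pipe.predict_proba(Xte)[:, 1], yte)
            res.tuned_params["rf"] = params
            imp = pipe.named_steps["model"].feature_importances_
            total = imp.sum()
            res.importances = pd.Series(imp / total if total > 0 else imp, index=X.columns)
        if "en" in models:
            pipe, params = tune_and_train(Xtr, ytr, "en", cv_folds, en_grid, seed)
            res.auc_en = evaluate_auc(pipe.predict_proba(Xte)[:, 1], yte)
            res.tuned_params["en"] = params
        results.append(res)
    return results


def grouped_importance(
    results: Sequence[SplitResult], groups: Mapping[str, str]
) -> ImportanceSummary:
    """Sum importances within feature groups per split; average per bin.

    ``groups`` maps every feature name to one of {sequence, vivo, vitro,
    insilico}. Per-bin means cover the vivo/vitro meta-gene bin features
    (names ``vivo_bin_NN`` / ``vitro_bin_NN``) averaged over splits.
    """
    rows = []
    bin_rows = []
    for res in results:
        if res.importances is None:
            continue
        sums: dict[str, float] = {"sequence": 0.0, "vivo": 0.0, "vitro": 0.0, "insilico": 0.0}
        for name, v in res.importances.items():
            if name not in groups:
                raise ValueError(f"feature {name!r} not in group registry")
            sums[groups[name]] += float(v)
        rows.append(pd.Series(sums, name=res.split_index))
        bin_rows.append(res.importances[[n for n in res.importances.index if _BIN_RE.match(n)]])
    if not rows:
        raise ValueError("no split carries importances")
    group_sums = pd.DataFrame(rows)
    per_split_bins = pd.DataFrame(bin_rows)
    mean_imp = per_split_bins.mean(axis=0)
    records: dict[int, dict[str, float]] = {}
    for name, v in mean_imp.items():
        cond, idx = _BIN_RE.match(name).groups()
        records.setdefault(int(idx), {})[cond] = float(v)
    bin_means = pd.DataFrame.from_dict(records, orient="index").sort_index()
    bin_means.index.name = "bin_index"
    return ImportanceSummary(group_sums=group_sums, bin_means=bin_means)


def compare_models(auc_a: Sequence[float], auc_b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided t-test on per-split AUC differences (a - b)."""
    a, b = np.asarray(auc_a, dtype=float), np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must have equal length (same splits)")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            warnings.warn("identical AUC vectors; t undefined")
            return math.nan, math.nan
        warnings.warn("zero variance of AUC differences; p reported as 0")
        return math.copysign(math.inf, float(d.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def split_table(results: Sequence[SplitResult]) -> pd.DataFrame:
    """Per-split result table (split_index, seed, AUCs, tuned params)."""
    return pd.DataFrame(
        {
            "split_index": [r.split_index for r in results],
            "seed": [r.seed for r in results],
            "auc_rf": [r.auc_rf for r in results],
            "auc_en": [r.auc_en for r in results],
            "tuned_params": [repr(r.tuned_params) for r in results],
        }
    ).set_index("split_index")
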
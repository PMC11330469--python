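"""Random-Forest classification over radiomic and/or CNN features.

Feature-level fusion concatenates hidden-layer CNN activations with the
handcrafted radiomic features; no scaling is applied because tree ensembles
are invariant to monotone transforms of individual columns.  Hyperparameters
come from an exhaustive grid (729 settings by default) selected by stratified
k-fold cross-validation on macro one-vs-rest AUC, and feature relevance is
ranked by permutation importance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class RFGrid:
    """The explored Random-Forest hyperparameter grid (Cartesian product)."""

    n_trees: tuple[int, ...] = (75, 150, 300)
    min_samples_leaf: tuple[int, ...] = (1, 2, 4)
    min_samples_split: tuple[int, ...] = (2, 4, 8)
    max_depth: tuple[int, ...] = (4, 8, 12)
    sample_proportion: tuple[float, ...] = (0.5, 0.75, 1.0)
    feature_proportion: tuple[float, ...] = (0.25, 0.5, 0.75)

    def settings(self) -> list[dict]:
        keys = (
            "n_trees",
            "min_samples_leaf",
            "min_samples_split",
            "max_depth",
            "sample_proportion",
            "feature_proportion",
        )
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(getattr(self, k) for k in keys))
        ]


#: A deliberately small sub-grid for desk-scale experiments.
SMALL_GRID = RFGrid(
    n_trees=(150,),
    min_samples_leaf=(1, 2),
    min_samples_split=(2,),
    max_depth=(8, 12),
    sample_proportion=(1.0,),
    feature_proportion=(0.5,),
)


def combine_features(radiomic: pd.DataFrame, cnn: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of two feature matrices (subjects aligned).

    The result carries per-column source tags in ``df.attrs['sources']``.
    """
    if len(cnn.columns) and not radiomic.index.equals(cnn.index):
        missing = sorted(
            set(radiomic.index).symmetric_difference(set(cnn.index))
        )
        raise ValueError(
            f"subject sets differ between feature matrices: {missing}"
            if missing
            else "subject ordering differs between feature matrices"
        )
    dup = sorted(set(radiomic.columns) & set(cnn.columns))
    if dup:
        raise ValueError(f"duplicated feature names across sources: {dup}")
    combined = pd.concat([radiomic, cnn], axis=1)
    sources = {c: "radiomic" for c in radiomic.columns}
    sources.update({c: "cnn" for c in cnn.columns})
    combined.attrs["sources"] = sources
    return combined


def _check_features(X: pd.DataFrame) -> None:
    bad = X.columns[X.isna().any()].tolist()
    if bad:
        raise ValueError(f"NaN values in feature column(s): {bad}")


def fit_rf(
    X: pd.DataFrame, y: np.ndarray, hyperparameters: dict, seed: int = 0
) -> RandomForestClassifier:
    """Fit a Random Forest with the package's hyperparameter naming.

    ``sample_proportion`` bounds the rows drawn (with replacement) per tree;
    ``feature_proportion`` the candidate features per split.
    """
    _check_features(X)
    hp = hyperparameters
    model = RandomForestClassifier(
        n_estimators=int(hp["n_trees"]),
        min_samples_leaf=int(hp["min_samples_leaf"]),
        min_samples_split=int(hp["min_samples_split"]),
        max_depth=int(hp["max_depth"]),
        max_features=float(hp["feature_proportion"]),
        bootstrap=True,
        max_samples=None
        if float(hp["sample_proportion"]) >= 1.0
        else float(hp["sample_proportion"]),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(), y)
    return model


def grid_search_rf(
    dev_features: pd.DataFrame,
    dev_labels: np.ndarray,
    grid: RFGrid | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search by stratified k-fold CV on macro OvR AUC.

    Returns the winning setting and the full cv record (one row per setting
    per fold).  Ties are broken toward the smaller model (fewer trees, then
    shallower), then grid order.
    """
    from .evaluation import ovr_auc

    grid = grid or RFGrid()
    _check_features(dev_features)
    y = np.asarray(dev_labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts < k].tolist()
        raise ValueError(
            f"class(es) {small} have fewer than k={k} members; "
            "stratified cross-validation is infeasible"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(dev_features, y))
    records = []
    for si, setting in enumerate(grid.settings()):
        for fi, (tr, va) in enumerate(folds):
            model = fit_rf(dev_features.iloc[tr], y[tr], setting, seed=seed)
            proba = model.predict_proba(dev_features.iloc[va].to_numpy())
            auc = ovr_auc(y[va], proba)
            records.append({"setting": si, **setting, "fold": fi, "val_auc": auc})
    record = pd.DataFrame(records)
    means = record.groupby("setting")["val_auc"].mean()
    settings = grid.settings()
    order = sorted(
        means.index,
        key=lambda s: (
            -means[s],
            settings[s]["n_trees"],
            settings[s]["max_depth"],
            s,
        ),
    )
    best = dict(settings[order[0]])
    return best, record


def permutation_importance(
    model: RandomForestClassifier,
    features: pd.DataFrame,
    labels: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance scored by macro OvR AUC drop.

    The importance of a column is the baseline score minus the mean score
    over ``n_repeats`` shuffles of that column; the output is sorted by
    descending importance (alphabetical tie-break) and includes the standard
    deviation over repeats.
    """
    from .evaluation import ovr_auc

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("permutation importance needs at least two classes")
    rng = np.random.default_rng(seed)
    Xnp = features.to_numpy().copy()
    baseline = ovr_auc(y, model.predict_proba(Xnp))
    rows = []
    for ci, col in enumerate(features.columns):
        drops = []
        saved = Xnp[:, ci].copy()
        for _ in range(n_repeats):
            Xnp[:, ci] = saved[rng.permutation(len(saved))]
            drops.append(baseline - ovr_auc(y, model.predict_proba(Xnp)))
        Xnp[:, ci] = saved
        rows.append(
            {
                "feature": col,
                "importance": float(np.mean(drops)),
                "importance_sd": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["importance", "feature"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)


def cv_permutation_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: RFGrid | None = None,
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on validation folds, averaged over k folds.

    Hyperparameters are grid-searched once on the full data by stratified
    k-fold CV; each fold's forest is then refit on the training portion and
    its columns permuted on the validation portion, so importances reflect
    held-out predictive value rather than training-set memorization.
    """
    y = np.asarray(y)
    best, _ = grid_search_rf(X, y, grid, k=k, seed=seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fi, (tr, va) in enumerate(cv.split(X, y)):
        model = fit_rf(X.iloc[tr], y[tr], best, seed=seed)
        imp = permutation_importance(
            model, X.iloc[va], y[va], n_repeats=n_repeats, seed=seed + fi
        )
        per_fold.append(imp.set_index("feature")["importance"])
    mean_imp = pd.concat(per_fold, axis=1).mean(axis=1)
    out = (
        mean_imp.rename("importance")
        .reset_index()
        .sort_values(["importance", "feature"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return out
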
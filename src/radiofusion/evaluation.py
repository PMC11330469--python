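"""Resampled evaluation protocol and corrected significance testing.

The protocol draws repeated stratified development(80%)/test(20%) splits of
the cohort, trains each model arm on identical splits (paired design),
scores held-out macro one-vs-rest AUC, summarizes each arm as mean with a
Student-t 95% confidence interval, and compares arms with the corrected
resampled t-test, whose variance term is inflated by n_test/n_train to
account for the overlap between resampled training sets (overlapping splits
violate the independence assumption of the classical paired t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic import SubjectVolume, largest_remainder_counts


@dataclass(frozen=True)
class SplitPlan:
    """Per-resample development/test subject-index lists."""

    resamples: tuple[tuple[np.ndarray, np.ndarray], ...]
    test_fraction: float
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.resamples)

    @property
    def train_test_ratio(self) -> float:
        """The designed n_test/n_train ratio (0.25 for an 80/20 split)."""
        return self.test_fraction / (1.0 - self.test_fraction)


def make_resamples(
    labels: Sequence, n: int = 25, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Draw ``n`` stratified dev/test splits, deterministic for a fixed seed.

    Per class, the test count is the largest-remainder share of
    ``test_fraction`` (never below one subject for classes of size >= 2), so
    realized test-class proportions are within one subject of the stratified
    targets and every class appears in every test set.
    """
    y = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        singletons = classes[counts < 2].tolist()
        raise ValueError(f"class(es) {singletons} have fewer than 2 members")
    # largest-remainder apportionment of the total test size across classes
    exact = counts * test_fraction
    n_test_per_class = np.maximum(np.floor(exact).astype(int), 1)
    total_target = int(round(len(y) * test_fraction))
    remainder = exact - np.floor(exact)
    for idx in np.argsort(-remainder, kind="stable"):
        if n_test_per_class.sum() >= total_target:
            break
        n_test_per_class[idx] += 1

    ss = np.random.SeedSequence(seed)
    resamples = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        test_idx: list[np.ndarray] = []
        for cls, n_test in zip(classes, n_test_per_class):
            members = np.nonzero(y == cls)[0]
            perm = rng.permutation(len(members))
            test_idx.append(members[perm[:n_test]])
        test = np.sort(np.concatenate(test_idx))
        dev = np.setdiff1d(np.arange(len(y)), test)
        resamples.append((dev, test))
    return SplitPlan(resamples=tuple(resamples), test_fraction=test_fraction, seed=seed)


def ovr_auc(labels: Sequence, probabilities: np.ndarray) -> float:
    """Macro one-vs-rest AUC: mean of per-class binary AUCs.

    Raises if any probability column's class is absent from ``labels`` (the
    binary AUC would be undefined).
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2:
        raise ValueError("probabilities must be (n_subjects, n_classes)")
    classes = np.arange(p.shape[1])
    present = np.unique(y)
    missing = sorted(set(classes) - set(present))
    if missing:
        raise ValueError(f"class(es) {missing} absent from labels; OvR AUC undefined")
    aucs = [roc_auc_score((y == c).astype(int), p[:, c]) for c in classes]
    return float(np.mean(aucs))


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and Student-t 95% CI of each arm over resamples.

    CI = mean +/- t_{0.975, n-1} * sd / sqrt(n).
    """
    if len(results) < 2:
        raise ValueError("summaries need at least 2 resamples")
    rows = []
    n = len(results)
    tq = stats.t.ppf(0.975, n - 1)
    for arm in results.columns:
        v = results[arm].to_numpy(dtype=float)
        mean = v.mean()
        half = tq * v.std(ddof=1) / np.sqrt(n)
        rows.append(
            {"arm": arm, "mean": mean, "ci_lower": mean - half, "ci_upper": mean + half,
             "n_resamples": n}
        )
    return pd.DataFrame(rows).set_index("arm")


def corrected_resampled_ttest(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    n_train: int,
    n_test: int,
    sided: str = "two",
) -> tuple[float, float]:
    """Corrected resampled t-test for paired per-resample metrics.

    t = mean(d) / sqrt((1/k + n_test/n_train) * var(d)) with d = a - b and
    the unbiased sample variance; p from Student t with k-1 degrees of
    freedom.  ``sided='greater'`` tests whether arm a beats arm b;
    ``'two'`` is the two-sided test.  In the n_test/n_train -> 0 limit the
    statistic reduces to the classical paired t.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if isinstance(metric_a, pd.Series) and isinstance(metric_b, pd.Series):
        if not metric_a.index.equals(metric_b.index):
            raise ValueError("unpaired inputs: resample indices differ between arms")
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired 1-D metric vectors of length >= 2")
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    k = len(a)
    d = a - b
    var = d.var(ddof=1)
    if var == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        warnings.warn("degenerate variance with nonzero mean difference; p := 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / np.sqrt((1.0 / k + n_test / n_train) * var)
    df = k - 1
    if sided == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif sided == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return float(t), float(p)


ARMS = ("radiomics", "cnn", "combined")


@dataclass
class ExperimentResult:
    """Per-resample AUCs, summaries, pairwise tests and full provenance."""

    per_resample: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: dict = dataclass_field(default_factory=dict)


def _dev_train_val_split(dev: np.ndarray, y_dev: np.ndarray, seed: int):
    """Single 5-part stratified split of the development set: 4 train, 1 val."""
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    tr, va = next(iter(cv.split(np.zeros(len(dev)), y_dev)))
    return dev[tr], dev[va]


def _tune_and_train_cnn(X, y, dev, seed, cnn_config, train_config, lr_grid):
    """Select the learning rate on one stratified dev split by validation loss."""
    from . import cnn as cnn_mod

    tr_idx, va_idx = _dev_train_val_split(dev, y[dev], seed)
    best = None
    for lr in lr_grid:
        tc = cnn_mod.TrainConfig(
            batch_size=train_config.batch_size,
            total_epochs=train_config.total_epochs,
            cosine_period=train_config.cosine_period,
            learning_rate=lr,
            momentum=train_config.momentum,
            seed=seed,
            input_channel_dropout_prob=train_config.input_channel_dropout_prob,
        )
        model = cnn_mod.build_model(cnn_config, seed=seed)
        trained = cnn_mod.train(model, (X[tr_idx], y[tr_idx]), (X[va_idx], y[va_idx]), tc)
        if best is None or trained.best_val_loss < best.best_val_loss:
            best = trained
    return best


def run_experiment(
    cohort: Sequence[SubjectVolume],
    arms: Sequence[str],
    plan: SplitPlan,
    *,
    feature_table: pd.DataFrame | None = None,
    bin_width: float = 0.25,
    feature_registry: Sequence[str] | None = None,
    rf_grid=None,
    rf_cv_folds: int = 5,
    cnn_config=None,
    train_config=None,
    lr_grid: Sequence[float] = (0.01,),
    sided: str = "greater",
    seed: int = 0,
) -> ExperimentResult:
    """Run the requested model arms on identical paired resamples.

    Arms: ``radiomics`` (Random Forest on handcrafted features, 5-fold CV
    hyperparameter search per development set), ``cnn`` (shallow 3D CNN,
    learning rate tuned on a single stratified split of the development set)
    and ``combined`` (hidden CNN activations concatenated with radiomic
    features, then the Random-Forest pipeline).  The combined arm reuses the
    CNN trained for the cnn arm on the same resample, frozen before any test
    subject is touched.
    """
    from . import cnn as cnn_mod
    from . import fusion
    from .radiomics import feature_table as make_feature_table

    arms = list(arms)
    unknown = [a for a in arms if a not in ARMS]
    if unknown:
        raise ValueError(f"unknown arm(s) {unknown}; valid arms: {ARMS}")
    rf_grid = rf_grid or fusion.SMALL_GRID
    cnn_config = cnn_config or cnn_mod.CNNConfig()
    train_config = train_config or cnn_mod.TrainConfig()

    need_radiomics = "radiomics" in arms or "combined" in arms
    need_cnn = "cnn" in arms or "combined" in arms
    feats = None
    if need_radiomics:
        feats = (
            feature_table
            if feature_table is not None
            else make_feature_table(cohort, feature_registry, bin_width)
        )
    if need_cnn:
        X, y = cnn_mod.cohort_to_arrays(cohort)
    else:
        from .synthetic import CLASS_NAMES

        y = np.array([CLASS_NAMES.index(s.label) for s in cohort])
        X = None

    ss = np.random.SeedSequence(seed)
    resample_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(plan.n_resamples)]
    records: dict[str, list[float]] = {a: [] for a in arms}
    chosen: list[dict] = []
    for r, (dev, test) in enumerate(plan.resamples):
        rseed = resample_seeds[r]
        prov: dict = {"resample": r, "seed": rseed}
        trained = None
        if need_cnn:
            trained = _tune_and_train_cnn(
                X, y, dev, rseed, cnn_config, train_config, lr_grid
            )
            prov["cnn_lr"] = trained.train_config.learning_rate
            prov["cnn_best_epoch"] = trained.best_epoch
        if "cnn" in arms:
            proba = cnn_mod.predict_proba(trained, X[test])
            records["cnn"].append(ovr_auc(y[test], proba))
        if "radiomics" in arms:
            best, _ = fusion.grid_search_rf(
                feats.iloc[dev], y[dev], rf_grid, k=rf_cv_folds, seed=rseed
            )
            prov["rf_radiomics"] = best
            model = fusion.fit_rf(feats.iloc[dev], y[dev], best, seed=rseed)
            proba = model.predict_proba(feats.iloc[test].to_numpy())
            records["radiomics"].append(ovr_auc(y[test], proba))
        if "combined" in arms:
            hidden = cnn_mod.extract_hidden_features(trained, X)
            cnn_feats = pd.DataFrame(
                hidden,
                index=feats.index,
                columns=[f"cnn_{i:03d}" for i in range(hidden.shape[1])],
            )
            combined = fusion.combine_features(feats, cnn_feats)
            best, _ = fusion.grid_search_rf(
                combined.iloc[dev], y[dev], rf_grid, k=rf_cv_folds, seed=rseed
            )
            prov["rf_combined"] = best
            model = fusion.fit_rf(combined.iloc[dev], y[dev], best, seed=rseed)
            proba = model.predict_proba(combined.iloc[test].to_numpy())
            records["combined"].append(ovr_auc(y[test], proba))
        chosen.append(prov)

    per_resample = pd.DataFrame(records)
    per_resample.index.name = "resample"
    summaries = summarize(per_resample)
    comp_rows = []
    n_train = len(plan.resamples[0][0])
    n_test = len(plan.resamples[0][1])
    for i, a in enumerate(arms):
        for b in arms[i + 1 :]:
            t, p = corrected_resampled_ttest(
                per_resample[a], per_resample[b], n_train, n_test, sided=sided
            )
            comp_rows.append(
                {"arm_a": a, "arm_b": b, "t": t, "p": p, "sided": sided}
            )
    comparisons = pd.DataFrame(comp_rows)
    provenance = {
        "seed": seed,
        "n_resamples": plan.n_resamples,
        "test_fraction": plan.test_fraction,
        "n_train": n_train,
        "n_test": n_test,
        "lr_grid": list(lr_grid),
        "per_resample": chosen,
    }
    return ExperimentResult(per_resample, summaries, comparisons, provenance)
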
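"""Can a CNN learn handcrafted radiomic feature values from the image?

The experiment ranks radiomic features by their permutation importance in the
Random-Forest classifier, then trains the same shallow 3D CNN — with a
single-output regression head and mean-squared-error loss — to predict each
feature's value directly from the masked volume.  Learnability is quantified
as the Pearson correlation between predicted and true values on held-out test
splits, averaged over resamples (paired across features).  Targets are
z-scored on the training split only, which keeps the MSE well-scaled across
features of very different magnitudes without affecting the correlation
(Pearson r is affine-invariant).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from .evaluation import SplitPlan, _dev_train_val_split
from .radiomics import FEATURE_CATEGORIES
from .synthetic import SubjectVolume


def select_target_features(importance_ranking: pd.DataFrame, k: int = 7) -> list[str]:
    """Top-k feature names from a permutation-importance ranking.

    Ties at the boundary are broken alphabetically (the ranking is already
    sorted that way); a tie crossing rank k is logged via a warning.
    """
    if k > len(importance_ranking):
        raise ValueError(
            f"k={k} exceeds the {len(importance_ranking)} ranked features"
        )
    ranked = importance_ranking.reset_index(drop=True)
    if k < len(ranked) and ranked.loc[k - 1, "importance"] == ranked.loc[k, "importance"]:
        warnings.warn(
            f"tie at rank {k} ({ranked.loc[k - 1, 'feature']} vs "
            f"{ranked.loc[k, 'feature']}); alphabetical tie-break applied"
        )
    return ranked["feature"].head(k).tolist()


def train_feature_regressor(
    feature_name: str,
    X: np.ndarray,
    y_class: np.ndarray,
    targets: np.ndarray,
    dev: np.ndarray,
    seed: int,
    cnn_config: cnn_mod.CNNConfig | None = None,
    train_config: cnn_mod.TrainConfig | None = None,
) -> tuple[cnn_mod.TrainedCNN, float, float]:
    """Train a single-output regression CNN for one radiomic feature.

    Targets are standardized using the mean/sd of the *training* portion of
    the development split; the (mu, sd) transform is returned so predictions
    can be mapped back to the original feature scale.
    """
    cnn_config = cnn_config or cnn_mod.CNNConfig(head="regression", n_outputs=1)
    if cnn_config.head != "regression":
        raise ValueError("feature regression requires a regression-head config")
    tc = train_config or cnn_mod.TrainConfig()
    tr_idx, va_idx = _dev_train_val_split(dev, y_class[dev], seed)
    mu = float(targets[tr_idx].mean())
    sd = float(targets[tr_idx].std(ddof=0))
    if sd < 1e-12:
        raise ValueError(
            f"feature {feature_name!r} is constant on the training split; "
            "a regression target must vary"
        )
    z = (targets - mu) / sd
    tc = cnn_mod.TrainConfig(
        batch_size=tc.batch_size,
        total_epochs=tc.total_epochs,
        cosine_period=tc.cosine_period,
        learning_rate=tc.learning_rate,
        momentum=tc.momentum,
        seed=seed,
        input_channel_dropout_prob=tc.input_channel_dropout_prob,
    )
    model = cnn_mod.build_model(cnn_config, seed=seed)
    trained = cnn_mod.train(model, (X[tr_idx], z[tr_idx]), (X[va_idx], z[va_idx]), tc)
    return trained, mu, sd


def evaluate_learnability(
    features: Sequence[str],
    cohort: Sequence[SubjectVolume],
    plan: SplitPlan,
    feature_values: pd.DataFrame,
    *,
    cnn_config: cnn_mod.CNNConfig | None = None,
    train_config: cnn_mod.TrainConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature, per-resample test correlation of CNN-predicted values.

    Returns ``(per_resample, summary)``: the first has one row per resample
    and one column per feature (Pearson r on the untouched test split, on the
    original feature scale); the second mirrors a results table with feature,
    category and mean correlation.  Zero-variance predictions are recorded as
    correlation 0 with a warning.
    """
    X, y_class = cnn_mod.cohort_to_arrays(cohort)
    ss = np.random.SeedSequence(seed)
    resample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(plan.n_resamples)
    ]
    results: dict[str, list[float]] = {f: [] for f in features}
    for fname in features:
        targets = feature_values[fname].to_numpy(dtype=np.float64)
        for r, (dev, test) in enumerate(plan.resamples):
            trained, mu, sd = train_feature_regressor(
                fname, X, y_class, targets, dev, resample_seeds[r],
                cnn_config, train_config,
            )
            pred_z = cnn_mod.predict_regression(trained, X[test])[:, 0]
            pred = pred_z * sd + mu
            truth = targets[test]
            if pred.std() < 1e-12 or truth.std() < 1e-12:
                warnings.warn(
                    f"feature {fname!r}, resample {r}: zero-variance "
                    "predictions or truths; correlation recorded as 0"
                )
                results[fname].append(0.0)
            else:
                results[fname].append(float(np.corrcoef(pred, truth)[0, 1]))
    per_resample = pd.DataFrame(results)
    per_resample.index.name = "resample"
    summary = pd.DataFrame(
        {
            "feature": list(features),
            "category": [FEATURE_CATEGORIES.get(f, "Unknown") for f in features],
            "mean_correlation": [float(np.mean(results[f])) for f in features],
            "n_resamples": plan.n_resamples,
        }
    )
    return per_resample, summary
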
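"""End-to-end orchestration of the four experiment arms.

Arms: A — shallow 3D CNN classification; B — Random-Forest classification on
handcrafted radiomic features; C — feature-level fusion of CNN hidden
activations with radiomic features; D — learnability regression (CNNs trained
to predict the values of the most important radiomic features).

A single YAML config drives everything.  Per-stage sub-seeds are spawned from
the master seed at fixed positions (cohort, split plan, classification arms,
importance ranking, learnability plan, learnability), so enabling or
disabling one arm never shifts the randomness of another.  All emitted
tables use fixed float formatting, making reruns byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cnn as cnn_mod
from . import fusion
from .evaluation import make_resamples, run_experiment
from .io import read_cohort, write_cohort
from .learnability import evaluate_learnability, select_target_features
from .radiomics import DEFAULT_FEATURES, feature_table
from .synthetic import (
    CohortConfig,
    ShapeEffect,
    SpatialEffect,
    TextureEffect,
    generate_cohort,
    labels_of,
)

ARM_LETTERS = {"A": "cnn", "B": "radiomics", "C": "combined", "D": "learnability"}

_FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid experiment config:\n  " + "\n  ".join(errors))


_DEFAULTS = {
    "master_seed": 0,
    "output_dir": "results",
    "arms": ["B"],
    "cohort": {},
    "splits": {"n_resamples": 25, "test_fraction": 0.2},
    "radiomics": {"bin_width": 0.25, "registry": None},
    "cnn": {"dropout_conv": 0.3, "dropout_fc": 0.3},
    "train": {"total_epochs": 10, "cosine_period": 5, "batch_size": 16,
              "lr_grid": [0.01]},
    "rf_grid": "small",
    "learnability": {"n_resamples": 10, "top_k": 2, "features": None},
    "write_volumes": False,
}


def _merge(defaults: dict, given: dict) -> dict:
    out = {}
    for key, dv in defaults.items():
        gv = given.get(key, dv)
        if isinstance(dv, dict) and isinstance(gv, dict):
            out[key] = {**dv, **gv}
        else:
            out[key] = gv
    for key in given:
        if key not in defaults:
            out[key] = given[key]
    return out


def validate_config(source) -> dict:
    """Normalize a config (path, YAML string or dict), raising all errors.

    Every violation is reported with its key path; defaults are filled in and
    echoed in the returned dict.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        raw = source
    else:
        raise ConfigError([f"config source not found or not a mapping: {source!r}"])
    errors: list[str] = []
    unknown = set(raw) - set(_DEFAULTS)
    for key in sorted(unknown):
        errors.append(f"{key}: unknown key")
    cfg = _merge(_DEFAULTS, {k: v for k, v in raw.items() if k in _DEFAULTS})
    arms = cfg["arms"]
    if not isinstance(arms, list) or not arms:
        errors.append("arms: must be a non-empty list drawn from A, B, C, D")
    else:
        bad = [a for a in arms if a not in ARM_LETTERS]
        if bad:
            errors.append(f"arms: unknown arm(s) {bad}; valid arms are A, B, C, D")
    tf = cfg["splits"].get("test_fraction")
    if not isinstance(tf, (int, float)) or not 0 < tf < 1:
        errors.append(f"splits.test_fraction: must be in (0, 1), got {tf!r}")
    nr = cfg["splits"].get("n_resamples")
    if not isinstance(nr, int) or nr < 2:
        errors.append(f"splits.n_resamples: must be an integer >= 2, got {nr!r}")
    if not isinstance(cfg["master_seed"], int):
        errors.append(f"master_seed: must be an integer, got {cfg['master_seed']!r}")
    bw = cfg["radiomics"].get("bin_width")
    if not isinstance(bw, (int, float)) or bw <= 0:
        errors.append(f"radiomics.bin_width: must be positive, got {bw!r}")
    if cfg["rf_grid"] not in ("small", "full") and not isinstance(cfg["rf_grid"], dict):
        errors.append(
            f"rf_grid: must be 'small', 'full' or a mapping of lists, got {cfg['rf_grid']!r}"
        )
    if errors:
        raise ConfigError(errors)
    return cfg


def _cohort_config(section: dict, seed: int) -> CohortConfig:
    kwargs = dict(section)
    kwargs.pop("directory", None)
    for name, cls in (
        ("shape_effect", ShapeEffect),
        ("texture_effect", TextureEffect),
        ("spatial_effect", SpatialEffect),
    ):
        if name in kwargs and isinstance(kwargs[name], dict):
            sub = {
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v
                for k, v in kwargs[name].items()
            }
            kwargs[name] = cls(**sub)
    for tup_field in ("class_proportions", "volume_shape", "voxel_spacing",
                      "channel_missing_prob"):
        if tup_field in kwargs and isinstance(kwargs[tup_field], list):
            kwargs[tup_field] = tuple(kwargs[tup_field])
    kwargs.setdefault("seed", seed)
    return CohortConfig(**kwargs)


def _rf_grid(spec) -> fusion.RFGrid:
    if spec == "small":
        return fusion.SMALL_GRID
    if spec == "full":
        return fusion.RFGrid()
    return fusion.RFGrid(**{k: tuple(v) for k, v in spec.items()})


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)


def run(source) -> dict:
    """Run the configured arms; returns a result bundle (paths + tables)."""
    cfg = validate_config(source)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(cfg["master_seed"])
    seeds = master.spawn(6)
    seed_of = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))

    # --- cohort -----------------------------------------------------------
    if cfg["cohort"].get("directory"):
        cohort = read_cohort(cfg["cohort"]["directory"])
    else:
        cohort = generate_cohort(_cohort_config(cfg["cohort"], seed_of(0)))
    labels = labels_of(cohort)
    manifest = pd.DataFrame(
        {"subject_id": [s.subject_id for s in cohort], "label": labels}
    )
    _write_csv(manifest, out / "manifest.csv", index=False)
    if cfg["write_volumes"]:
        write_cohort(cohort, out / "cohort")

    bundle: dict = {"output_dir": str(out), "n_subjects": len(cohort)}
    arms = [ARM_LETTERS[a] for a in cfg["arms"]]
    class_arms = [a for a in arms if a != "learnability"]

    # --- shared inputs ----------------------------------------------------
    registry = cfg["radiomics"]["registry"] or list(DEFAULT_FEATURES)
    bin_width = float(cfg["radiomics"]["bin_width"])
    feats = None
    if set(arms) & {"radiomics", "combined", "learnability"}:
        feats = feature_table(cohort, registry, bin_width)
        _write_csv(feats, out / "features.csv")
        bundle["features"] = feats

    tr = cfg["train"]
    train_config = cnn_mod.TrainConfig(
        batch_size=int(tr["batch_size"]),
        total_epochs=int(tr["total_epochs"]),
        cosine_period=int(tr["cosine_period"]),
    )
    cnn_config = cnn_mod.CNNConfig(
        dropout_conv=float(cfg["cnn"]["dropout_conv"]),
        dropout_fc=float(cfg["cnn"]["dropout_fc"]),
    )
    grid = _rf_grid(cfg["rf_grid"])

    # --- classification arms (A/B/C) --------------------------------------
    if class_arms:
        plan = make_resamples(
            labels,
            n=int(cfg["splits"]["n_resamples"]),
            test_fraction=float(cfg["splits"]["test_fraction"]),
            seed=seed_of(1),
        )
        result = run_experiment(
            cohort,
            class_arms,
            plan,
            feature_table=feats,
            bin_width=bin_width,
            rf_grid=grid,
            cnn_config=cnn_config,
            train_config=train_config,
            lr_grid=tuple(tr["lr_grid"]),
            seed=seed_of(2),
        )
        _write_csv(result.per_resample, out / "results.csv")
        _write_csv(result.summaries, out / "summary.csv")
        _write_csv(result.comparisons, out / "comparisons.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "summaries": result.summaries.to_dict(orient="index"),
                    "comparisons": result.comparisons.to_dict(orient="records"),
                },
                indent=2,
                sort_keys=True,
                default=float,
            )
        )
        bundle["classification"] = result

    # --- learnability arm (D) ---------------------------------------------
    if "learnability" in arms:
        lcfg = cfg["learnability"]
        if lcfg["features"]:
            targets = list(lcfg["features"])
        else:
            ranking = fusion.cv_permutation_importance(
                feats, np.asarray(pd.Categorical(labels).codes),
                grid, seed=seed_of(3),
            )
            _write_csv(ranking, out / "importance.csv", index=False)
            targets = select_target_features(ranking, k=int(lcfg["top_k"]))
        lplan = make_resamples(
            labels,
            n=int(lcfg["n_resamples"]),
            test_fraction=float(cfg["splits"]["test_fraction"]),
            seed=seed_of(4),
        )
        reg_config = cnn_mod.CNNConfig(
            head="regression",
            n_outputs=1,
            dropout_conv=float(cfg["cnn"]["dropout_conv"]),
            dropout_fc=float(cfg["cnn"]["dropout_fc"]),
        )
        per_resample, summary = evaluate_learnability(
            targets, cohort, lplan, feats,
            cnn_config=reg_config, train_config=train_config, seed=seed_of(5),
        )
        _write_csv(per_resample, out / "learnability.csv")
        _write_csv(summary, out / "learnability_summary.csv", index=False)
        bundle["learnability"] = (per_resample, summary)

    provenance = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "output_dir"},
        "stage_seeds": {
            name: seed_of(i)
            for i, name in enumerate(
                ["cohort", "plan", "classification", "importance",
                 "learnability_plan", "learnability"]
            )
        },
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str)
    )
    bundle["provenance"] = provenance
    return bundle
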
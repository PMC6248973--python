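"""End-to-end experiment orchestration.

Chains the pieces the way the study design prescribes: feature extraction
for every reference pair, a stratified 70:30 development/test split,
column standardization, repeated cross-validated training of the four
model families evaluated on the held-out test set, rule-based comparator
evaluation on the whole dataset, ANOVA + Tukey HSD on the AUROC samples,
and feature-importance aggregation.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr_model import Cohort, ReferencePair, split_train_test
from .extraction import ExtractionContext
from .features_ml import (
    MODEL_FAMILIES,
    ModelSpec,
    assemble_features,
    compare_auroc,
    comparator_evaluation,
    extract_pair_features,
    feature_importance,
    repeated_cv_evaluation,
    standardize_features,
)

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "write_report"]


def run_experiment(
    cohort: Cohort,
    reference: Sequence[ReferencePair],
    seed: int = 0,
    reps: int = 10,
    folds: int = 10,
    leakage_mode: str = "pooled",
    families: Sequence[str] = MODEL_FAMILIES,
    k_controls: int = 4,
    two_by_two: str = "matched",
    train_frac: float = 0.7,
) -> dict:
    """Run the full evaluation experiment; returns a result bundle.

    ``leakage_mode='pooled'`` standardizes features over the entire dataset
    (the published preprocessing); ``'strict'`` fits the scaler on the
    development rows only.
    """
    if leakage_mode not in ("pooled", "strict"):
        raise ValueError("leakage_mode must be 'pooled' or 'strict'")
    t0 = time.perf_counter()
    ctx = ExtractionContext(cohort)
    extractions = extract_pair_features(
        ctx,
        [rp.pair for rp in reference],
        seed=seed,
        k_controls=k_controls,
        two_by_two=two_by_two,
    )
    logger.info("extraction: %.1fs", time.perf_counter() - t0)

    raw, mask, y = assemble_features(extractions, reference)
    dev, test = split_train_test(list(reference), frac=train_frac, seed=seed)
    pos = {id(rp) for rp in dev}
    dev_rows = np.array([i for i, rp in enumerate(reference) if id(rp) in pos])
    test_rows = np.array([i for i, rp in enumerate(reference) if id(rp) not in pos])

    X = standardize_features(raw, fit_rows=None if leakage_mode == "pooled" else dev_rows)
    X_dev, y_dev = X.iloc[dev_rows].to_numpy(), y[dev_rows]
    X_test, y_test = X.iloc[test_rows].to_numpy(), y[test_rows]

    specs = [ModelSpec(f, seed=seed) for f in families]
    t0 = time.perf_counter()
    cv = repeated_cv_evaluation(
        X_dev, y_dev, specs, X_test, y_test, reps=reps, folds=folds, seed=seed,
        keep_models=True,
    )
    logger.info("repeated CV: %.1fs", time.perf_counter() - t0)

    auroc_groups = {f: cv[f]["table"]["auroc"].to_numpy() for f in cv}
    anova = compare_auroc(auroc_groups) if len(cv) > 1 else None
    importance = feature_importance({f: cv[f]["models"] for f in cv})
    comparators = comparator_evaluation(extractions, reference)

    return {
        "extractions": extractions,
        "features_raw": raw,
        "features": X,
        "mask": mask,
        "labels": y,
        "dev_rows": dev_rows,
        "test_rows": test_rows,
        "cv": cv,
        "anova": anova,
        "importance": importance,
        "comparators": comparators,
    }


def write_report(results: dict, out_dir: str | Path) -> None:
    """Write features.csv, metrics.json, tukey.csv and importance.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    feats = results["features_raw"].copy()
    feats["label"] = results["labels"]
    feats.to_csv(out / "features.csv")

    metrics = {}
    for family, res in results["cv"].items():
        s = res["summary"]
        metrics[family] = {
            col: {"mean": float(s.loc["mean", col]), "sd": float(s.loc["std", col])}
            for col in s.columns
        }
    metrics["comparators"] = {
        name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
        for name, row in results["comparators"].iterrows()
    }
    if results["anova"] is not None:
        metrics["anova"] = {
            "f": results["anova"]["anova_f"],
            "p": results["anova"]["anova_p"],
        }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

    if results["anova"] is not None:
        results["anova"]["tukey"].to_csv(out / "tukey.csv", index=False)
    results["importance"].to_csv(out / "importance.csv")
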
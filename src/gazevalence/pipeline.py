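"""End-to-end experiment drivers.

Two experiments over a labelled gaze dataset (read from CSV or
generated synthetically):

* **baseline** — classify valence from each feature block individually,
  from the full 872-dim concatenation, and from each of the six
  mean-value features, for every requested SVM kernel;
* **fusion** — classify from the full vector after each requested
  reduction/selection scheme (PCA, SVD, SFS, SBS, GA, PSO), and rank
  the feature blocks by how much of them the wrapper searches keep.

Both write CSV/JSON reports into the configured output directory and
are deterministic under the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, selection
from .evaluation import CVPlan, FoldResult, aggregate, make_cv_plan, train_eval
from .features import (
    BLOCK_SIZES, MEAN_FEATURE_NAMES, block_slices, feature_matrix, mean_features,
)
from .gaze_data import GazeRecordset, read_fixation_table
from .selection import (
    SelectionMask, VarianceReducer, contribution_analysis,
    ga_select, make_validation_objective, pso_select, sequential_select,
)
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "load_recordset", "run_baseline", "run_fusion"]

WRAPPER_METHODS = ("sfs", "sbs", "ga", "pso")
REDUCTION_METHODS = ("pca", "svd")


@dataclass
class ExperimentConfig:
    """Configuration shared by the two experiment drivers."""

    # input: either CSV paths or a synthetic config
    fixations_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticConfig | None = None

    feature_set: str = "both"            # histogram | mean | both
    kernels: tuple[str, ...] = ("linear", "rbf", "poly")
    selection_methods: tuple[str, ...] = ("pca", "svd", "sfs", "sbs", "ga", "pso")
    n_repeats: int = 10
    n_folds: int = 10
    ratios: tuple[float, float, float] = (0.9, 0.05, 0.05)
    variance_threshold: float = 0.9
    selection_granularity: str = "block"   # block (fast) | dimension (full study)
    n_selection_folds: int = 10            # folds the wrapper searches run on
    search_params: dict = field(default_factory=dict)  # overrides for GA/PSO
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.feature_set not in ("histogram", "mean", "both"):
            raise ValueError("feature_set must be histogram, mean or both")
        if not self.kernels:
            raise ValueError("at least one kernel is required")
        unknown = set(self.selection_methods) - set(WRAPPER_METHODS + REDUCTION_METHODS)
        if unknown:
            raise ValueError(f"unknown selection method(s) {sorted(unknown)}")


def load_recordset(config: ExperimentConfig) -> GazeRecordset:
    if config.synthetic is not None:
        return generate(config.synthetic)
    if config.fixations_path is None:
        raise ValueError("either a synthetic config or a fixation CSV is required")
    return read_fixation_table(config.fixations_path, config.labels_path)


def _summarize(feature: str, kernel: str, results: list[FoldResult]) -> dict:
    agg = aggregate(results)
    return {
        "feature": feature,
        "kernel": kernel,
        "mean_bookmaker": agg["mean_bookmaker"],
        "se_bookmaker": agg["se_bookmaker"],
        "mean_accuracy_pct": 100.0 * agg["mean_accuracy"],
        "se_accuracy_pct": 100.0 * agg["se_accuracy"],
        "n_folds": agg["n_folds"],
    }


def _write_confusions(results_by_key: dict, out_dir: Path, stem: str) -> None:
    rows = []
    for (feature, kernel), results in results_by_key.items():
        pooled = np.sum([r.confusion for r in results], axis=0)
        for i, true_cls in enumerate(evaluation.CLASSES):
            rows.append(
                {"feature": feature, "kernel": kernel, "true_class": true_cls,
                 **{f"pred_{c}": int(pooled[i, j])
                    for j, c in enumerate(evaluation.CLASSES)}}
            )
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_confusions.csv", index=False)


def run_baseline(config: ExperimentConfig) -> pd.DataFrame:
    """Experiment: per-feature baseline.

    One row per (feature, kernel): the ten blocks, the full 872-dim
    set, and the six mean-value features, scored by mean Bookmaker and
    accuracy (%) with standard errors over all repeat x fold results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rs = load_recordset(config)
    labels = np.array(rs.labels())
    plan = make_cv_plan(
        labels, n_repeats=config.n_repeats, n_folds=config.n_folds,
        ratios=config.ratios, seed=config.seed,
    )
    candidates: list[tuple[str, np.ndarray]] = []
    if config.feature_set in ("histogram", "both"):
        fm = feature_matrix(rs)
        fm.to_csv(out_dir / "feature_matrix.csv")
        slices = block_slices()
        X = fm.to_numpy()
        for name, _ in BLOCK_SIZES:
            candidates.append((name, X[:, slices[name]]))
        candidates.append(("full_set", X))
    if config.feature_set in ("mean", "both"):
        mf = mean_features(rs)
        mf.to_csv(out_dir / "mean_features.csv")
        for name in MEAN_FEATURE_NAMES:
            candidates.append((f"mean_{name}", mf[[name]].to_numpy()))

    rows, confusions = [], {}
    for feature, X in candidates:
        for kernel in config.kernels:
            results = train_eval(X, labels, plan, kernel=kernel)
            rows.append(_summarize(feature, kernel, results))
            confusions[(feature, kernel)] = results
            logger.info("baseline %s / %s: bm=%.3f", feature, kernel,
                        rows[-1]["mean_bookmaker"])
    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "baseline_results.csv", index=False)
    _write_confusions(confusions, out_dir, "baseline")
    with open(out_dir / "baseline_summary.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    return report


def _wrapper_search(method: str, objective, granularity: str, n_dims: int,
                    seed: int, params: dict) -> SelectionMask:
    if method == "sfs":
        return sequential_select(objective=objective, direction="forward",
                                 granularity=granularity, n_dims=n_dims)
    if method == "sbs":
        return sequential_select(objective=objective, direction="backward",
                                 granularity=granularity, n_dims=n_dims)
    if method == "ga":
        return ga_select(objective=objective, granularity=granularity,
                         n_dims=n_dims, seed=seed, **params.get("ga", {}))
    if method == "pso":
        return pso_select(objective=objective, granularity=granularity,
                          n_dims=n_dims, seed=seed, **params.get("pso", {}))
    raise ValueError(f"unknown wrapper method {method!r}")


def _mask_columns(mask: SelectionMask) -> np.ndarray:
    if mask.granularity == "dimension":
        return mask.mask
    cols = np.zeros(sum(n for _, n in BLOCK_SIZES), dtype=bool)
    slices = block_slices()
    for bit, (name, _) in zip(mask.mask, BLOCK_SIZES):
        if bit:
            cols[slices[name]] = True
    return cols


def run_fusion(config: ExperimentConfig) -> dict:
    """Experiment: feature combination under reduction/selection.

    Decomposition methods (PCA/SVD) are refitted inside every fold of
    the full plan.  Wrapper methods (SFS/SBS/GA/PSO) search a mask on
    each of the first ``n_selection_folds`` folds' train/validation
    splits and are scored on those folds' test sets; their masks feed
    the block-contribution report.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rs = load_recordset(config)
    labels = np.array(rs.labels())
    fm = feature_matrix(rs)
    X = fm.to_numpy()
    plan = make_cv_plan(
        labels, n_repeats=config.n_repeats, n_folds=config.n_folds,
        ratios=config.ratios, seed=config.seed,
    )

    rows, confusions = [], {}
    masks: list[SelectionMask] = []

    for kernel in config.kernels:
        full_results = train_eval(X, labels, plan, kernel=kernel)
        rows.append(_summarize("full_set", kernel, full_results))
        confusions[("full_set", kernel)] = full_results
        for method in config.selection_methods:
            if method in REDUCTION_METHODS:
                factory = lambda m=method: VarianceReducer(
                    threshold=config.variance_threshold, method=m
                )
                results = train_eval(
                    X, labels, plan, kernel=kernel, transform_factory=factory
                )
            else:
                results = []
                for fa in plan.assignments[: config.n_selection_folds]:
                    objective = make_validation_objective(
                        X, labels, fa, kernel=kernel,
                        granularity=config.selection_granularity,
                    )
                    mask = _wrapper_search(
                        method, objective, config.selection_granularity,
                        _n_dims(config, X), config.seed + fa.repeat * 100 + fa.fold,
                        config.search_params,
                    )
                    mask.repeat, mask.fold = fa.repeat, fa.fold
                    masks.append(mask)
                    results.extend(
                        train_eval(
                            X[:, _mask_columns(mask)], labels,
                            _single_fold_plan(plan, fa), kernel=kernel,
                        )
                    )
            rows.append(_summarize(method, kernel, results))
            confusions[(method, kernel)] = results
            logger.info("fusion %s / %s: bm=%.3f", method, kernel,
                        rows[-1]["mean_bookmaker"])

    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "fusion_results.csv", index=False)
    _write_confusions(confusions, out_dir, "fusion")

    contribution = None
    if masks:
        contribution = contribution_analysis(masks)
        contribution.to_csv(out_dir / "contribution_report.csv")
        mask_rows = [
            {"method": m.method, "repeat": m.repeat, "fold": m.fold,
             "granularity": m.granularity, "objective_value": m.objective_value,
             "mask": "".join("1" if b else "0" for b in m.mask)}
            for m in masks
        ]
        pd.DataFrame(mask_rows).to_csv(out_dir / "selection_masks.csv", index=False)
    with open(out_dir / "fusion_summary.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    return {"report": report, "masks": masks, "contribution": contribution}


def _n_dims(config: ExperimentConfig, X: np.ndarray) -> int:
    return len(BLOCK_SIZES) if config.selection_granularity == "block" else X.shape[1]


def _single_fold_plan(plan: CVPlan, fa) -> CVPlan:
    return CVPlan(
        n_repeats=1, n_folds=1, ratios=plan.ratios, seed=plan.seed,
        classes=plan.classes, assignments=[fa],
    )
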
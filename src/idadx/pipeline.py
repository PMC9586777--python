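"""Full-experiment orchestration: dataset variants × resampling strategies.

Mirrors the multistep expert-system design: the input table is cleaned with
each configured outlier method (the uncleaned original is always kept as a
variant), each variant is summarized and screened with Boruta, and every
variant × resampling strategy cell runs an MCC-maximizing grid search under
repeated stratified CV.  All randomness flows from one root seed through
named substreams, so any cell can be re-run in isolation and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boruta import boruta
from .datasets import LabeledDataset, correlation_matrix, read_dataset, summarize
from .evaluate import METRICS, CVReport, HyperGrid, grid_search
from .outliers import (
    attach_class_counts,
    flag_by_score_z,
    nof_scores,
    rdos_scores,
    remove_outliers,
    zscore_outliers,
)
from .resample import STRATEGIES, ResamplingPlan
from .simulate import generate, ida_preset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "overview_table"]

OUTLIER_METHODS = ("zscore", "rdos", "nof")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    input_path: str | None = None  # CSV path; None -> synthetic preset
    preset_n: int = 516
    label_column: str = "DD"
    outlier_methods: tuple[str, ...] = OUTLIER_METHODS
    zscore_threshold: float = 3.0
    score_z_threshold: float = 3.0
    rdos_k: int = 5
    rdos_h: float | str = "auto"
    boruta_runs: int = 100
    boruta_alpha: float = 0.01
    boruta_trees: int = 500
    keep_all_features: bool = False
    strategies: tuple[str, ...] = STRATEGIES
    smote_k: int = 5
    ef_m: int = 3
    ef_folds: int = 5
    grid: HyperGrid = field(default_factory=HyperGrid)
    folds: int = 10
    repeats: int = 5
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for m in self.outlier_methods:
            if m not in OUTLIER_METHODS:
                raise ValueError(f"unknown outlier method {m!r}")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    datasets: dict[str, LabeledDataset]
    summaries: dict[str, object]
    correlations: dict[str, np.ndarray]
    outlier_reports: dict[str, object]
    boruta_results: dict[str, object]
    cv_reports: dict[tuple[str, str], CVReport]  # (dataset variant, strategy)
    best_params: dict[tuple[str, str], object]
    errors: dict[tuple[str, str], str]

    def overview(self) -> pd.DataFrame:
        return overview_table(self.cv_reports)


def _substreams(seed: int) -> dict[str, int]:
    """Named independent seeds derived from the root seed."""
    names = ("data", "boruta", "resample", "cv")
    states = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in states)))


def _clean_variants(ds: LabeledDataset, cfg: ExperimentConfig):
    variants = {"original": ds}
    reports = {}
    for method in cfg.outlier_methods:
        if method == "zscore":
            rep = zscore_outliers(ds.features, threshold=cfg.zscore_threshold)
        elif method == "rdos":
            rep = flag_by_score_z(
                rdos_scores(ds.features, k=cfg.rdos_k, h=cfg.rdos_h),
                threshold=cfg.score_z_threshold,
            )
        else:
            rep = flag_by_score_z(nof_scores(ds.features), threshold=cfg.score_z_threshold)
        rep = attach_class_counts(rep, ds.labels)
        reports[method] = rep
        variants[method] = remove_outliers(ds, rep, name=method)
    return variants, reports


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the whole grid of dataset variants × resampling strategies.

    Per-cell failures are recorded and do not stop the remaining cells.
    """
    seeds = _substreams(cfg.seed)
    if cfg.input_path is not None:
        ds = read_dataset(cfg.input_path, label_column=cfg.label_column)
    else:
        ds = generate(ida_preset(seed=seeds["data"], n=cfg.preset_n))

    variants, outlier_reports = _clean_variants(ds, cfg)
    summaries = {name: summarize(v) for name, v in variants.items()}
    correlations = {}
    boruta_results = {}
    cv_reports: dict[tuple[str, str], CVReport] = {}
    best_params = {}
    errors: dict[tuple[str, str], str] = {}

    for name, variant in variants.items():
        try:
            correlations[name] = correlation_matrix(variant)
        except ValueError as exc:
            errors[(name, "correlation")] = str(exc)
        try:
            bres = boruta(
                variant, runs=cfg.boruta_runs, alpha=cfg.boruta_alpha,
                rng_seed=seeds["boruta"], n_estimators=cfg.boruta_trees,
            )
            boruta_results[name] = bres
            selected = bres.selected(keep_tentative=True)
        except ValueError as exc:
            errors[(name, "boruta")] = str(exc)
            selected = list(variant.feature_names)
        if cfg.keep_all_features:
            selected = list(variant.feature_names)
        if not selected:
            logger.warning("%s: no feature survived screening; keeping all", name)
            selected = list(variant.feature_names)
        cols = [variant.feature_names.index(f) for f in selected]
        modelling_ds = LabeledDataset(
            variant.features[:, cols], tuple(selected), variant.labels, name=variant.name
        )

        for strategy in cfg.strategies:
            plan = ResamplingPlan(
                strategy=strategy, smote_k=cfg.smote_k,
                ef_m=cfg.ef_m, ef_folds=cfg.ef_folds, seed=seeds["resample"],
            )
            try:
                point, report = grid_search(
                    modelling_ds, plan, cfg.grid,
                    folds=cfg.folds, repeats=cfg.repeats, seed=seeds["cv"],
                )
                cv_reports[(name, strategy)] = report
                best_params[(name, strategy)] = point
            except (ValueError, RuntimeError) as exc:
                logger.warning("cell (%s, %s) failed: %s", name, strategy, exc)
                errors[(name, strategy)] = str(exc)

    result = ExperimentResult(
        config=cfg, datasets=variants, summaries=summaries,
        correlations=correlations, outlier_reports=outlier_reports,
        boruta_results=boruta_results, cv_reports=cv_reports,
        best_params=best_params, errors=errors,
    )
    if cfg.output_dir is not None:
        write_reports(result, Path(cfg.output_dir))
    return result


def overview_table(cells: dict[tuple[str, str], CVReport]) -> pd.DataFrame:
    """Best strategy per dataset × metric; ties are marked jointly ('a|b')."""
    if not cells:
        raise ValueError("no completed cells")
    datasets = sorted({d for d, _ in cells})
    rows = []
    for d in datasets:
        row = {"dataset": d}
        for metric in METRICS:
            vals = {s: rep.metric_means[metric] for (dd, s), rep in cells.items() if dd == d}
            if not vals:
                row[metric] = ""
                continue
            best = max(vals.values())
            winners = [s for s, v in vals.items() if np.isclose(v, best, rtol=0, atol=1e-12)]
            row[metric] = "|".join(sorted(winners))
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


def format_cv_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """'mean ± sd' layout, one row per metric, one column per strategy."""
    cols = {}
    for strategy, rep in reports.items():
        cols[strategy] = [
            f"{rep.metric_means[m]:.4f} ± {rep.metric_sds[m]:.4f}" for m in METRICS
        ]
    return pd.DataFrame(cols, index=list(METRICS))


def write_reports(result: ExperimentResult, outdir: Path) -> None:
    """Emit CSV/text tables and a JSON provenance manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    for name, summ in result.summaries.items():
        summ.to_frame().to_csv(outdir / f"summary_{name}.csv")
    for name, R in result.correlations.items():
        names = list(result.datasets[name].feature_names)
        pd.DataFrame(R, index=names, columns=names).to_csv(outdir / f"correlation_{name}.csv")
    for name, bres in result.boruta_results.items():
        pd.DataFrame(
            {"decision": bres.decisions, "hits": bres.hits}
        ).to_csv(outdir / f"boruta_{name}.csv")
        pd.DataFrame(bres.importance_history).to_csv(
            outdir / f"boruta_history_{name}.csv", index=False
        )
    by_dataset: dict[str, dict[str, CVReport]] = {}
    for (d, s), rep in result.cv_reports.items():
        by_dataset.setdefault(d, {})[s] = rep
    for d, reps in by_dataset.items():
        format_cv_table(reps).to_csv(outdir / f"performance_{d}.csv")
    if result.cv_reports:
        result.overview().to_csv(outdir / "overview.csv")

    import sklearn
    import xgboost

    manifest = {
        "idadx": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
        "config": _config_json(result.config),
        "best_params": {
            f"{d}/{s}": list(p) for (d, s), p in result.best_params.items()
        },
        "errors": {f"{d}/{s}": msg for (d, s), msg in result.errors.items()},
        "outliers_removed": {
            m: rep.removed_by_class for m, rep in result.outlier_reports.items()
        },
    }
    (outdir / "provenance.json").write_text(json.dumps(manifest, indent=2, default=str))


def _config_json(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["grid"] = dataclasses.asdict(cfg.grid)
    return d
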
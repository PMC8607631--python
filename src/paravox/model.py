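"""Model/Results interface over the detection engine.

`VoiceDetectionModel` is built from a feature table and a classifier
family; `fit()` runs the full pipeline — repeated RFECV feature selection,
grid-search tuning, then the repeated stratified holdout evaluation — and
returns a `VoiceDetectionResults` carrying per-iteration metric samples,
their means and standard deviations, the averaged ROC band, the selected
feature subset, tuned hyperparameters and a run-time breakdown.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import detection
from .cohort import FeatureTable
from .detection import EvaluationReport, SelectionResult


class VoiceDetectionModel:
    """Parkinson's-detection pipeline bound to a subject-level feature table.

    Parameters
    ----------
    table : FeatureTable
        Subject-level (aggregated) feature table; labels PD/healthy.
    family : str
        Classifier family, one of :data:`paravox.detection.FAMILIES`.
    grid : dict, optional
        Hyperparameter grid; defaults to the family's documented grid.
    selection_iterations, selection_folds : int
        Repeats and folds of the RFECV stage (defaults 100 and 5).
    eval_iterations, test_fraction : int, float
        Holdout repeats and test share of the evaluation stage
        (defaults 1000 and 0.25).
    """

    def __init__(
        self,
        table: FeatureTable,
        family: str = "passive_aggressive",
        grid: dict | None = None,
        selection_iterations: int = 100,
        selection_folds: int = 5,
        eval_iterations: int = 1000,
        test_fraction: float = 0.25,
    ):
        if family not in detection.FAMILIES:
            raise ValueError(
                f"unknown family {family!r}; choose from {detection.FAMILIES}"
            )
        self.table = table
        self.family = family
        self.grid = grid
        self.selection_iterations = selection_iterations
        self.selection_folds = selection_folds
        self.eval_iterations = eval_iterations
        self.test_fraction = test_fraction

    @classmethod
    def from_csv(cls, path: str | Path, aggregate: bool = True, **kwargs):
        """Build from a per-recording CSV; triplicates are averaged per
        subject unless ``aggregate`` is False."""
        table = FeatureTable.from_csv(path)
        if aggregate:
            table = table.aggregate_by_subject()
        return cls(table, **kwargs)

    def select_features(self, seed: int = 0) -> SelectionResult:
        return detection.rfecv_select(
            self.table,
            self.family,
            n_iterations=self.selection_iterations,
            k=self.selection_folds,
            seed=seed,
        )

    def tune(self, selection: SelectionResult | list[str] | None, seed: int = 0) -> dict:
        table = self.table
        if selection is not None:
            names = (
                selection.selected_features
                if isinstance(selection, SelectionResult)
                else list(selection)
            )
            table = table.subset_features(names)
        return detection.grid_search(
            table, self.family, grid=self.grid, k=self.selection_folds, seed=seed
        )

    def fit(
        self,
        seed: int = 0,
        selected_features: list[str] | None = None,
        hyperparams: dict | None = None,
    ) -> "VoiceDetectionResults":
        """Run selection -> tuning -> evaluation and return the results.

        Passing ``selected_features``/``hyperparams`` freezes those stages
        (the cross-database transfer protocol: no re-selection, no
        re-tuning on the new cohort).
        """
        timings: dict[str, float] = {}
        selection = None
        if selected_features is None:
            t0 = time.perf_counter()
            selection = self.select_features(seed=seed)
            timings["selection"] = time.perf_counter() - t0
            selected_features = selection.selected_features
        if hyperparams is None:
            t0 = time.perf_counter()
            hyperparams = self.tune(selected_features, seed=seed)
            timings["grid_search"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        report = detection.evaluate(
            self.table,
            selected_features,
            self.family,
            hyperparams,
            n_iterations=self.eval_iterations,
            test_fraction=self.test_fraction,
            seed=seed,
        )
        timings["classification"] = time.perf_counter() - t0
        report.runtime_s = timings
        return VoiceDetectionResults(self, report, selection, hyperparams)

    def transfer_fit(
        self, results: "VoiceDetectionResults", seed: int = 0
    ) -> "VoiceDetectionResults":
        """Evaluate this model's cohort with a feature subset and
        hyperparameters frozen from another cohort's fitted results."""
        return self.fit(
            seed=seed,
            selected_features=list(results.selected_features),
            hyperparams=dict(results.hyperparams),
        )


@dataclass
class VoiceDetectionResults:
    """Fitted-pipeline results: metric samples, ROC band and provenance."""

    model: VoiceDetectionModel
    report: EvaluationReport
    selection: SelectionResult | None
    hyperparams: dict

    @property
    def selected_features(self) -> list[str]:
        return self.report.selected_features

    @property
    def metrics(self) -> dict[str, tuple[float, float]]:
        return self.report.metric_summary()

    def compare(self, other: "VoiceDetectionResults", equal_var: bool = True):
        """Per-metric Student's t-test against another fitted result."""
        return detection.compare_reports(
            self.report, other.report, equal_var=equal_var
        )

    def summary(self) -> str:
        lines = [
            "Voice condition analysis — repeated stratified holdout",
            "=" * 58,
            f"classifier family : {self.model.family}",
            f"subjects           : {self.model.table.n_rows} "
            f"(PD={int(self.model.table.y.sum())}, "
            f"healthy={int((1 - self.model.table.y).sum())})",
            f"iterations         : {self.report.n_iterations} "
            f"(test fraction {self.model.test_fraction:.2f})",
            f"selected features  : {len(self.selected_features)} -> "
            + ", ".join(self.selected_features),
            f"hyperparameters    : {self.hyperparams}",
            "-" * 58,
            f"{'metric':<14}{'mean':>10}{'sd':>10}",
        ]
        for name, (mean, sd) in self.metrics.items():
            lines.append(f"{name:<14}{mean:>10.4f}{sd:>10.4f}")
        if self.report.runtime_s:
            lines.append("-" * 58)
            for stage, secs in self.report.runtime_s.items():
                lines.append(f"{stage:<14}{secs:>10.2f} s")
        return "\n".join(lines)

    def plot_roc_band(self, ax=None):
        """Mean ROC curve with a +-1 sd band on the fixed FPR grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        r = self.report
        lo = np.clip(r.mean_tpr - r.sd_tpr, 0, 1)
        hi = np.clip(r.mean_tpr + r.sd_tpr, 0, 1)
        ax.fill_between(r.fpr_grid, lo, hi, color="0.85", label="±1 sd")
        ax.plot(r.fpr_grid, r.mean_tpr, color="tab:blue", label="mean ROC")
        ax.plot([0, 1], [0, 1], ls="--", color="0.5", lw=0.8)
        auc_mean, auc_sd = self.metrics["auc"]
        ax.set_xlabel("FPR (1 − specificity)")
        ax.set_ylabel("TPR (sensitivity)")
        ax.set_title(f"{self.model.family}: AUC {auc_mean:.3f} ± {auc_sd:.3f}")
        ax.legend(loc="lower right")
        return ax

    def to_json(self, path: str | Path) -> None:
        """Dump the full report, all per-iteration samples included."""
        r = self.report
        payload = {
            "family": r.family,
            "hyperparams": {k: v for k, v in r.hyperparams.items()},
            "selected_features": r.selected_features,
            "per_iteration": {
                "accuracy": r.accuracy.tolist(),
                "sensitivity": r.sensitivity.tolist(),
                "specificity": r.specificity.tolist(),
                "auc": r.auc.tolist(),
            },
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
            "roc": {
                "fpr_grid": r.fpr_grid.tolist(),
                "mean_tpr": r.mean_tpr.tolist(),
                "sd_tpr": r.sd_tpr.tolist(),
            },
            "runtime_s": r.runtime_s,
            "selection": None
            if self.selection is None
            else {
                "per_iteration_optimal_counts": self.selection.per_iteration_optimal_counts,
                "aggregated_ranking": self.selection.aggregated_ranking,
                "final_count": self.selection.final_count,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
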
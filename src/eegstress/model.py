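"""Top-level modelling interface: screen, classify, summarise.

:class:`StressClassificationModel` bundles a participants x 45 feature
matrix with binary stress/control labels; :meth:`fit` runs the t-test
screening and the cross-validated classifier comparison and returns a
:class:`StressClassificationResults` carrying the screening table, the
subset x classifier accuracy grid, the per-cell metric reports and a
printable summary.

Typical use::

    cohort = generate_cohort(GeneratorConfig(seed=7))
    model = StressClassificationModel.from_cohort(cohort, labeling_mode="expert")
    results = model.fit()
    print(results.summary())
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import (
    ClassifierSpec,
    CVConfig,
    CVResult,
    compare_feature_sets,
)
from .features import feature_matrix
from .labeling import build_ground_truth
from .selection import (
    FeatureTestResult,
    screen_features,
    screening_frame,
    selected_features,
)

#: Beyond this many screened-in features the subset grid collapses to
#: singletons + the full set (2^k - 1 subsets would explode).
_MAX_EXHAUSTIVE_SUBSETS = 4


def _default_subsets(selected: list[str]) -> list[list[str]]:
    if len(selected) <= _MAX_EXHAUSTIVE_SUBSETS:
        subsets = []
        for r in range(1, len(selected) + 1):
            subsets.extend([list(c) for c in combinations(selected, r)])
        return subsets
    return [[f] for f in selected] + [list(selected)]


class StressClassificationModel:
    """Stress-vs-control analysis over a named feature matrix.

    Parameters
    ----------
    features
        participants x features frame (canonical 45 columns when built
        from recordings, but any named columns work).
    labels
        Binary array aligned with the rows: control 0, stress 1.
    alpha
        Screening significance level.
    specs
        Classifier suite; defaults to all five families with their
        standard grids.
    cv
        Cross-validation protocol; stratified nested 10-fold by default.
    subsets
        Feature subsets for the comparison grid; defaults to every
        non-empty combination of the screened-in features (capped).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray,
        alpha: float = 0.05,
        specs: Optional[Sequence[ClassifierSpec]] = None,
        cv: Optional[CVConfig] = None,
        subsets: Optional[Sequence[Sequence[str]]] = None,
    ) -> None:
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels are misaligned")
        self.alpha = alpha
        self.specs = list(specs) if specs is not None else ClassifierSpec.default_suite()
        self.cv = cv if cv is not None else CVConfig()
        self.subsets = [list(s) for s in subsets] if subsets is not None else None

    @classmethod
    def from_cohort(cls, cohort, labeling_mode: str = "expert", **kwargs):
        """Build the model from a synthetic cohort's recordings and labels."""
        from .preprocessing import remove_dc_offset

        ids, labels = build_ground_truth(cohort.participants, mode=labeling_mode)
        cleaned = {
            pid: remove_dc_offset(cohort.recordings[pid])[0] for pid in ids
        }
        features = feature_matrix(cleaned).loc[ids]
        return cls(features, labels, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str, **kwargs):
        """Build from a tidy frame with the label column inline."""
        labels = frame[label_col].to_numpy()
        return cls(frame.drop(columns=[label_col]), labels, **kwargs)

    def fit(self) -> "StressClassificationResults":
        screening = screen_features(self.features, self.labels, alpha=self.alpha)
        selected = selected_features(screening)
        subsets = self.subsets
        if subsets is None:
            subsets = _default_subsets(selected) if selected else []
        if subsets:
            accuracy, cell_results = compare_feature_sets(
                self.features, self.labels, subsets, self.specs, self.cv
            )
        else:
            accuracy = pd.DataFrame(columns=[s.kind for s in self.specs], dtype=float)
            cell_results = {}
        return StressClassificationResults(
            model=self,
            screening_results=screening,
            selected=selected,
            accuracy_table=accuracy,
            cell_results=cell_results,
        )


class StressClassificationResults:
    """Fitted screening + classification results with a text summary."""

    def __init__(
        self,
        model: StressClassificationModel,
        screening_results: list[FeatureTestResult],
        selected: list[str],
        accuracy_table: pd.DataFrame,
        cell_results: dict[tuple[str, str], CVResult],
    ) -> None:
        self.model = model
        self.screening_results = screening_results
        self.selected = selected
        self.accuracy_table = accuracy_table
        self.cell_results = cell_results

    @property
    def screening(self) -> pd.DataFrame:
        """Per-feature t, p, significance (and supplementary BH) table."""
        return screening_frame(self.screening_results)

    @property
    def metrics(self) -> pd.DataFrame:
        """All five metrics per (subset, classifier) cell."""
        rows = []
        for (subset, kind), result in self.cell_results.items():
            row = {"features": subset, "classifier": kind}
            row.update(result.metrics.as_dict())
            row["fold_mean_accuracy"] = result.fold_mean_accuracy
            rows.append(row)
        return pd.DataFrame(rows)

    def best(self) -> Optional[tuple[str, str, float]]:
        """(subset, classifier, accuracy %) of the best cell, if any."""
        if self.accuracy_table.empty:
            return None
        stacked = self.accuracy_table.stack()
        (subset, kind) = stacked.idxmax()
        return subset, kind, float(stacked.max())

    def summary(self) -> str:
        n = len(self.model.labels)
        n_stress = int(self.model.labels.sum())
        lines = [
            "Stress classification results",
            "=" * 64,
            f"Samples: {n} ({n - n_stress} control, {n_stress} stress)   "
            f"Features: {self.model.features.shape[1]}   "
            f"alpha = {self.model.alpha}",
            f"CV: {self.model.cv.n_folds}-fold, "
            f"{'stratified' if self.model.cv.stratified else 'unstratified'}, "
            f"{'nested' if self.model.cv.nested else 'flat'} grid search, "
            f"seed {self.model.cv.seed}",
            "-" * 64,
            f"Screened-in features (p < {self.model.alpha}):",
        ]
        if self.selected:
            screen = self.screening
            for name in self.selected:
                lines.append(f"  {name:<24s} p = {screen.loc[name, 'p']:.4g}")
        else:
            lines.append("  (none)")
        lines.append("-" * 64)
        if not self.accuracy_table.empty:
            lines.append("Pooled CV accuracy (%) by feature set and classifier:")
            lines.append(self.accuracy_table.round(2).to_string())
            best = self.best()
            if best:
                lines.append(
                    f"Best: {best[1]} on {{{best[0]}}} at {best[2]:.2f}% accuracy"
                )
        else:
            lines.append("No classification run (no features selected).")
        lines.append("=" * 64)
        return "\n".join(lines)
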
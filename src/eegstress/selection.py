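"""Univariate feature screening with the two-sample t-test.

Every feature is tested for a stress-vs-control mean difference with
the classic pooled-variance (Student) two-sample t-test, two sided,
df = n1 + n2 - 2, at significance level 0.05 by default.  No multiplicity
correction is applied to the selection itself — the screening mirrors a
per-feature significance readout — but a Benjamini–Hochberg adjusted
column is carried alongside as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bands import ASYMMETRY_ORDER, FEATURE_BAND_ORDER, FEATURE_CHANNEL_ORDER


@dataclass(frozen=True)
class FeatureTestResult:
    """One feature's screening outcome."""

    feature_name: str
    mean_control: float
    mean_stress: float
    t_statistic: float
    p_value: float
    significant: bool


def two_sample_ttest(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default.

    Degenerate inputs with zero variance in both groups return
    ``(0, 1)`` when the means agree and ``(±inf, 0)`` otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"each group needs at least 2 values (got {x.size} and {y.size})"
        )
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def screen_features(
    feature_matrix: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[FeatureTestResult]:
    """Screen every feature column for a group difference.

    Parameters
    ----------
    feature_matrix
        participants x features frame in canonical column order.
    labels
        Binary array aligned with the rows: control 0, stress 1.
    alpha
        Per-feature significance level; a feature is selected iff
        ``p < alpha``.
    """
    labels = np.asarray(labels)
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if len(labels) != len(feature_matrix):
        raise ValueError("labels and feature rows are misaligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("screening needs both classes present")
    control = feature_matrix.loc[labels == 0]
    stress = feature_matrix.loc[labels == 1]
    results = []
    for name in feature_matrix.columns:
        t, p = two_sample_ttest(
            control[name].to_numpy(), stress[name].to_numpy(), equal_var=equal_var
        )
        results.append(
            FeatureTestResult(
                feature_name=name,
                mean_control=float(control[name].mean()),
                mean_stress=float(stress[name].mean()),
                t_statistic=t,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return results


def selected_features(results: list[FeatureTestResult]) -> list[str]:
    return [r.feature_name for r in results if r.significant]


def screening_frame(results: list[FeatureTestResult]) -> pd.DataFrame:
    """Tidy per-feature screening table with a supplementary BH column.

    The ``p_bh`` column is a Benjamini–Hochberg adjustment carried for
    reference only; selection always uses the raw p-values.
    """
    frame = pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "mean_control": [r.mean_control for r in results],
            "mean_stress": [r.mean_stress for r in results],
            "t": [r.t_statistic for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("feature")
    frame["p_bh"] = stats.false_discovery_control(frame["p"].to_numpy(), method="bh")
    return frame


def screening_report(results: list[FeatureTestResult]) -> pd.DataFrame:
    """P-values pivoted into the channels x bands report layout.

    Rows are the five channels (plus an ``asymmetries`` row); columns
    the eight per-channel features, then the five asymmetry indices.
    Cells not applicable to a row are NaN.
    """
    p = {r.feature_name: r.p_value for r in results}
    table = pd.DataFrame(
        index=list(FEATURE_CHANNEL_ORDER) + ["asymmetries"],
        columns=list(FEATURE_BAND_ORDER) + list(ASYMMETRY_ORDER),
        dtype=float,
    )
    for ch in FEATURE_CHANNEL_ORDER:
        for band in FEATURE_BAND_ORDER:
            key = f"{band}_{ch}"
            if key in p:
                table.loc[ch, band] = p[key]
    for name in ASYMMETRY_ORDER:
        if name in p:
            table.loc["asymmetries", name] = p[name]
    return table
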
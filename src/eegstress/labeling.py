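"""Group assignment from perceived-stress scores and expert evaluation.

Two labeling routes produce the stress/control ground truth:

* **PSS thresholding.**  From the cohort's PSS-10 total scores (each in
  0–40) a pair of cut points is derived as ``mu ± sigma/2``.  Scores
  strictly below the lower cut point are control (A), strictly above the
  upper cut point stress (B), and everything between is neutral (X) and
  excluded from classification.
* **Expert labels.**  A psychologist's A/B/X assignment made from a
  symptom interview together with the score.  These are ingested as
  data, never inferred — there is no computational definition of the
  interview.

σ defaults to the population standard deviation (divisor n); the sample
formula is available via ``ddof=1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io import ParticipantRecord

logger = logging.getLogger(__name__)


class GroupLabel(str, Enum):
    """Closed label vocabulary: A control, B stress, X neutral."""

    CONTROL = "A"
    STRESS = "B"
    NEUTRAL = "X"


@dataclass(frozen=True)
class PSSThresholds:
    """The mu ± sigma/2 cut points on the PSS score axis."""

    mu: float
    sigma: float
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")


def compute_thresholds(scores: Sequence[float], ddof: int = 0) -> PSSThresholds:
    """Derive the two stress/control cut points from a score list.

    Parameters
    ----------
    scores
        At least two PSS totals.
    ddof
        0 (default) for the population standard deviation, 1 for the
        sample formula.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 scores to set thresholds, got {arr.size}")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=ddof))
    return PSSThresholds(mu=mu, sigma=sigma, t_low=mu - sigma / 2, t_high=mu + sigma / 2)


def label_score(score: float, thresholds: PSSThresholds) -> GroupLabel:
    """Label a single score; boundary scores are neutral (strict inequalities)."""
    if score < thresholds.t_low:
        return GroupLabel.CONTROL
    if score > thresholds.t_high:
        return GroupLabel.STRESS
    return GroupLabel.NEUTRAL


def assign_pss_labels(
    records: Sequence["ParticipantRecord"], thresholds: PSSThresholds
) -> dict[str, GroupLabel]:
    """Label every participant by thresholding their PSS score."""
    return {r.id: label_score(r.pss_score, thresholds) for r in records}


def build_ground_truth(
    records: Sequence["ParticipantRecord"], mode: str
) -> tuple[list[str], np.ndarray]:
    """Binary classification truth under the chosen labeling mode.

    Neutral (X) participants are excluded.  Returns participant ids in
    input order and an int array with control → 0, stress → 1.

    Parameters
    ----------
    mode
        ``"pss"`` to use the threshold labels, ``"expert"`` for the
        psychologist's labels.
    """
    if mode not in ("pss", "expert"):
        raise ValueError(f"labeling mode must be 'pss' or 'expert', got {mode!r}")
    attr = "pss_label" if mode == "pss" else "expert_label"
    labels = [getattr(r, attr) for r in records]
    if all(lab is None for lab in labels):
        raise ValueError(f"no {mode} labels present in the participant table")
    ids: list[str] = []
    binary: list[int] = []
    for rec, lab in zip(records, labels):
        if lab is None or lab is GroupLabel.NEUTRAL:
            continue
        ids.append(rec.id)
        binary.append(1 if lab is GroupLabel.STRESS else 0)
    if not ids:
        logger.warning("ground truth (%s mode) is empty: all participants neutral", mode)
    return ids, np.asarray(binary, dtype=int)


def count_label_disagreements(records: Sequence["ParticipantRecord"]) -> int:
    """Number of participants whose PSS label differs from the expert label."""
    for r in records:
        if r.pss_label is None or r.expert_label is None:
            raise ValueError(f"participant {r.id}: both label columns must be populated")
    return sum(1 for r in records if r.pss_label is not r.expert_label)


def label_counts(labels: Iterable[GroupLabel]) -> dict[str, int]:
    """Count labels per group, always reporting all of A, B, X."""
    counts = {lab.value: 0 for lab in GroupLabel}
    for lab in labels:
        counts[GroupLabel(lab).value] += 1
    return counts
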
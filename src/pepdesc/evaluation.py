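"""Precision–recall evaluation of protein-level scores against ground truth.

Any method is evaluated through a per-protein ranking score: |DE-score| for
the peptide-level scorer (its binary calls use |score| > 0.3), 1 − p for
p-value methods. Curves sweep every distinct score value, grouping ties into
a single operating point; precision = TP/(TP+FP) and recall = TP/n_true at
each point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import PepdescError, ValidationError, _sep_for, logger

__all__ = [
    "GroundTruth",
    "PRCurve",
    "read_ground_truth",
    "write_ground_truth",
    "ranking_score",
    "precision_recall",
    "max_f_score",
    "tp_at_precision",
    "call_changing",
]

LABEL_CHANGING = "changing"
LABEL_STABLE = "stable"

#: default binary-call threshold on |protein DE-score| (strictly above calls)
DEFAULT_SCORE_CALL_THRESHOLD = 0.3


@dataclass
class GroundTruth:
    """True per-protein labels and log2 fold changes.

    labels:
        Series accession -> {"changing", "stable"}.
    true_log2_fold_change:
        Series accession -> signed log2(group1/group2) fold change
        (0 for stable proteins).
    """

    labels: pd.Series
    true_log2_fold_change: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {LABEL_CHANGING, LABEL_STABLE}
        if bad:
            raise ValidationError(f"unknown truth labels: {sorted(bad)}")
        if not self.true_log2_fold_change.index.equals(self.labels.index):
            raise ValidationError("truth fold-change index must match labels")

    @property
    def n_changing(self) -> int:
        return int((self.labels == LABEL_CHANGING).sum())


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a truth TSV with columns protein_accession, label, true_log2_fc."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)), encoding="utf-8")
    for c in ("protein_accession", "label", "true_log2_fc"):
        if c not in df.columns:
            raise ValidationError(f"truth table lacks column {c!r}")
    idx = pd.Index(df["protein_accession"].astype(str), name="protein_accession")
    return GroundTruth(
        labels=pd.Series(df["label"].to_numpy(), index=idx, name="label"),
        true_log2_fold_change=pd.Series(
            df["true_log2_fc"].to_numpy(dtype=float), index=idx, name="true_log2_fc"),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame({
        "protein_accession": truth.labels.index,
        "label": truth.labels.to_numpy(),
        "true_log2_fc": truth.true_log2_fold_change.to_numpy(),
    }).to_csv(path, sep="\t", index=False)


@dataclass
class PRCurve:
    """Precision–recall curve over distinct ranking-score thresholds."""

    thresholds: np.ndarray  # descending distinct scores
    precision: np.ndarray
    recall: np.ndarray
    tp: np.ndarray  # true-positive count at each threshold
    n_true: int
    n_total: int


def ranking_score(scores: pd.DataFrame) -> pd.Series:
    """Method-appropriate ranking score from a score table.

    Uses |de_score| when a ``de_score`` column exists, else 1 − p_value.
    """
    idx = pd.Index(scores["protein_accession"].astype(str))
    if "de_score" in scores.columns:
        return pd.Series(scores["de_score"].to_numpy(dtype=float), index=idx).abs()
    if "p_value" in scores.columns:
        return pd.Series(1.0 - scores["p_value"].to_numpy(dtype=float), index=idx)
    raise ValidationError("score table has neither de_score nor p_value")


def precision_recall(scores: pd.Series, truth: GroundTruth) -> PRCurve:
    """PR curve of a per-protein ranking score against the ground truth.

    Scored proteins missing from the truth are dropped with a warning;
    requires at least one true changing protein among the scored set.
    """
    scores = scores.astype(float)
    covered = scores.index.isin(truth.labels.index)
    if not covered.all():
        logger.warning("%d scored proteins lack truth labels; dropped",
                       int((~covered).sum()))
        scores = scores[covered]
    y = (truth.labels.loc[scores.index] == LABEL_CHANGING).to_numpy()
    if y.sum() == 0:
        raise PepdescError("ground truth contains no changing protein")
    s = scores.to_numpy()
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tp_cum = np.cumsum(y)
    # one operating point per distinct score: index of the last tied element
    # (comparison, not diff: diff of tied infinities is NaN)
    last = np.r_[np.nonzero(s[:-1] != s[1:])[0], s.size - 1]
    tp = tp_cum[last]
    n_pred = last + 1
    return PRCurve(
        thresholds=s[last],
        precision=tp / n_pred,
        recall=tp / y.sum(),
        tp=tp,
        n_true=int(y.sum()),
        n_total=int(y.size),
    )


def max_f_score(curve: PRCurve) -> float:
    """Maximum F1 = 2PR/(P+R) over the curve (points with P+R=0 skipped)."""
    p, r = curve.precision, curve.recall
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return float(f.max()) if f.size else 0.0


def tp_at_precision(curve: PRCurve, floor: float = 0.9) -> int:
    """Maximum true-positive count where precision strictly exceeds ``floor``."""
    if not (0 < floor < 1):
        raise ValidationError("precision floor must be in (0, 1)")
    ok = curve.precision > floor
    return int(curve.tp[ok].max()) if ok.any() else 0


def call_changing(
    scores: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_CALL_THRESHOLD,
    alpha: float = 0.05,
) -> pd.Series:
    """Binary changing/stable calls at the default operating point.

    DE-score methods call |score| strictly above ``score_threshold``;
    p-value methods call p < alpha.
    """
    idx = pd.Index(scores["protein_accession"].astype(str))
    if "de_score" in scores.columns:
        called = np.abs(scores["de_score"].to_numpy(dtype=float)) > score_threshold
    else:
        called = scores["p_value"].to_numpy(dtype=float) < alpha
    return pd.Series(called, index=idx, name="called_changing")
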
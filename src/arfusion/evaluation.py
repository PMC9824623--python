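"""ChIP-Seq gold standard construction and ROC/AUPR evaluation.

Every called peak is a positive binding event; its positive sequence is the
100 bp centred on the summit (50 bases each side of the signal maximum).
The null class is a set of randomly placed, non-overlapping intervals of the
same mean width as the peaks.  Classifier scores over these two classes feed
the ROC (AUC) and precision-recall (AUPR) summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_curve

from .io_formats import PeakRecord, SequenceRecord

__all__ = [
    "GoldRecord",
    "RocResult",
    "build_gold_standard",
    "generate_controls",
    "roc_auc",
    "pr_aupr",
]

logger = logging.getLogger(__name__)

POSITIVE_FLANK = 50  # bases kept on each side of the peak summit


@dataclass(frozen=True)
class GoldRecord:
    """A labelled gold-standard interval with its extracted sequence."""

    seq_id: str
    start: int
    end: int
    label: int
    sequence: str

    @property
    def width(self) -> int:
        return self.end - self.start


def build_gold_standard(
    peaks: list[PeakRecord], genome: list[SequenceRecord], flank: int = POSITIVE_FLANK
) -> list[GoldRecord]:
    """Extract the ``2*flank`` bp window around each peak summit as a positive.

    Peaks without a called summit fall back to the interval midpoint; windows
    running past a sequence edge are skipped with a warning.
    """
    by_id = {rec.id: rec for rec in genome}
    out = []
    skipped = 0
    for peak in peaks:
        rec = by_id.get(peak.chrom)
        if rec is None:
            raise ValueError(f"peak {peak.name!r} references unknown sequence {peak.chrom!r}")
        lo = peak.summit - flank
        hi = peak.summit + flank
        if lo < 0 or hi > len(rec):
            skipped += 1
            continue
        out.append(GoldRecord(peak.chrom, lo, hi, 1, rec.sequence[lo:hi]))
    if skipped:
        logger.warning("skipped %d peak(s) whose summit window exceeds sequence bounds", skipped)
    if not out:
        raise ValueError("no extractable peaks")
    return out


def generate_controls(
    peaks: list[PeakRecord],
    genome: list[SequenceRecord],
    count: int,
    seed: int,
    max_tries_per_control: int = 10_000,
) -> list[GoldRecord]:
    """Place ``count`` random control intervals of the peaks' mean width.

    Controls avoid every peak and each other (rejection sampling, reproducible
    for a given seed); chromosomes are drawn proportionally to their number of
    placeable positions.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    if not peaks:
        raise ValueError("need peaks to match the control width")
    width = int(round(float(np.mean([p.width for p in peaks]))))
    rng = np.random.default_rng(seed)

    taken: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        taken.setdefault(p.chrom, []).append((p.start, p.end))

    capacity = np.array([max(len(r) - width + 1, 0) for r in genome], dtype=float)
    if capacity.sum() <= 0:
        raise ValueError(f"no sequence long enough for {width} bp controls")
    weights = capacity / capacity.sum()

    controls: list[GoldRecord] = []
    tries = 0
    budget = max_tries_per_control * count
    while len(controls) < count:
        if tries >= budget:
            raise RuntimeError(
                f"placed only {len(controls)}/{count} controls after {tries} tries"
            )
        tries += 1
        ridx = int(rng.choice(len(genome), p=weights))
        rec = genome[ridx]
        if len(rec) < width:
            continue
        start = int(rng.integers(0, len(rec) - width + 1))
        end = start + width
        clash = any(s < end and start < e for s, e in taken.get(rec.id, []))
        if clash:
            continue
        taken.setdefault(rec.id, []).append((start, end))
        controls.append(GoldRecord(rec.id, start, end, 0, rec.sequence[start:end]))
    return controls


@dataclass
class RocResult:
    """ROC curve with its area.

    ``auc`` is the rank (Mann-Whitney concordance) statistic, ties counting
    one half; ``auc_trapezoid`` integrates the plotted curve and agrees with
    it to numerical precision.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_trapezoid: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for binary labels.

    The scalar AUC is the Mann-Whitney concordance probability (rank formula);
    the stored curve comes from threshold sweeping with trapezoidal area.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores, method="average")
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores)
    auc_trap = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc), auc_trapezoid=auc_trap)


def pr_aupr(scores, labels) -> float:
    """Area under the precision-recall curve by the step-wise rule
    (no interpolation), i.e. average precision."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("need at least one positive label")
    return float(average_precision_score(labels, scores))
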
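"""Decision-level fusion of the three spectral modes.

Each mode's classifier votes a freshness day per test unit; the
majority label wins, and when all three modes disagree the SWIR
prediction is used (the mode that consistently scores highest on its
own).  Also provides the repeated-measurement majority-vote accuracy
booster and a consolidated per-fillet report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .classification import (
    ConfusionMatrix,
    confusion_from_predictions,
    grouped_accuracy,
    tolerance_accuracy,
)
from .containers import SWIR


@dataclass
class ModePredictions:
    """Aligned per-unit predictions of one spectral mode."""

    mode: str
    predicted_day: np.ndarray
    true_day: np.ndarray
    level: str = "voxel"  # or "fillet"

    def __post_init__(self) -> None:
        self.predicted_day = np.asarray(self.predicted_day)
        self.true_day = np.asarray(self.true_day)
        if len(self.predicted_day) != len(self.true_day):
            raise ValueError("predicted and true labels differ in length")


@dataclass
class FusionResult:
    """Fused labels, tie-break flags and the fused confusion matrix."""

    fused_day: np.ndarray
    tie_break_used: np.ndarray
    confusion: ConfusionMatrix


def fuse_votes(fl: ModePredictions, vis: ModePredictions,
               swir: ModePredictions, tiebreak_mode: str = SWIR,
               class_days=None) -> FusionResult:
    """Majority vote across the three modes with a tie-break mode.

    Per unit: any label carrying at least two of the three votes wins;
    when all three disagree, the tie-break mode's label (SWIR by
    default) is used.  Truth labels must agree across modes since units
    are index-aligned.
    """
    by_mode = {p.mode: p for p in (fl, vis, swir)}
    if tiebreak_mode not in by_mode:
        raise ValueError(f"tie-break mode {tiebreak_mode!r} not among inputs")
    n = len(fl.predicted_day)
    if not (len(vis.predicted_day) == len(swir.predicted_day) == n):
        raise ValueError("mode prediction lengths differ")
    if not (
        np.array_equal(fl.true_day, vis.true_day)
        and np.array_equal(fl.true_day, swir.true_day)
    ):
        raise ValueError("true labels disagree across modes")
    votes = np.stack(
        [fl.predicted_day, vis.predicted_day, swir.predicted_day]
    )
    tiebreak = by_mode[tiebreak_mode].predicted_day
    fused = np.empty(n, dtype=votes.dtype)
    tie_used = np.zeros(n, dtype=bool)
    for i in range(n):
        labels, counts = np.unique(votes[:, i], return_counts=True)
        if counts.max() >= 2:
            fused[i] = labels[np.argmax(counts)]
        else:
            fused[i] = tiebreak[i]
            tie_used[i] = True
    days = tuple(class_days) if class_days is not None else tuple(
        sorted(set(np.unique(fl.true_day)) | set(np.unique(fused)))
    )
    cm = confusion_from_predictions(fl.true_day, fused, days)
    return FusionResult(fused_day=fused, tie_break_used=tie_used, confusion=cm)


def repeat_measure_accuracy(p: float, n: int = 3) -> float:
    """Accuracy of a strict-majority vote over n independent measurements.

    Probability that more than half of ``n`` independent per-measurement
    verdicts (each correct with probability ``p``) are correct:
    ``sum_{k > n/2} C(n, k) p^k (1-p)^(n-k)``.  Boosts any per-measurement
    accuracy above one half; e.g. three measurements at 95% exceed 99%.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    if n < 1 or n % 2 == 0:
        raise ValueError("n must be an odd positive count")
    return float(binom.sf(n // 2, n, p))


def aggregate_to_fillet(predictions: ModePredictions,
                        fillet_day_ids) -> ModePredictions:
    """Collapse voxel-level predictions to one verdict per fillet-day.

    The per-unit verdict is the modal predicted day among the unit's
    voxels (ties to the smallest day).  ``fillet_day_ids`` assigns each
    voxel to its fillet-day unit.
    """
    ids = np.asarray(fillet_day_ids)
    units = sorted(set(ids.tolist()))
    pred, true = [], []
    for u in units:
        sel = ids == u
        labels, counts = np.unique(predictions.predicted_day[sel],
                                   return_counts=True)
        pred.append(labels[np.argmax(counts)])
        t = np.unique(predictions.true_day[sel])
        if len(t) != 1:
            raise ValueError(f"unit {u!r} mixes true days {t}")
        true.append(t[0])
    return ModePredictions(
        mode=predictions.mode,
        predicted_day=np.array(pred),
        true_day=np.array(true),
        level="fillet",
    )


# ---------------------------------------------------------------------------
# reporting

#: day -> grade maps used for coarse accuracy reporting
def default_groupings(class_days) -> dict:
    """Two- and three-grade freshness groupings for a day-class set.

    Fresh covers days up to 5; in the three-grade map the first spoilt
    day is 'fairly fresh' and later days are 'spoilt'.
    """
    days = sorted(class_days)
    spoilt = [d for d in days if d > 5]
    two = {d: ("fresh" if d <= 5 else "spoilt") for d in days}
    three = {d: "fresh" for d in days if d <= 5}
    if spoilt:
        three[spoilt[0]] = "fairly_fresh"
        for d in spoilt[1:]:
            three[d] = "spoilt"
    return {"two_grade": two, "three_grade": three}


def _metrics(cm: ConfusionMatrix, groupings: dict) -> dict:
    out = {
        "exact_accuracy": cm.accuracy(),
        "tolerance_1day_accuracy": tolerance_accuracy(cm, 1),
    }
    for name, grouping in groupings.items():
        out[f"{name}_accuracy"] = grouped_accuracy(cm, grouping)
    return out


def fillet_report(mode_results: dict, fused: FusionResult,
                  groupings: dict | None = None) -> dict:
    """Consolidated report: per-mode and fused accuracy families.

    ``mode_results`` maps mode name to a :class:`ConfusionMatrix`.
    Returns a JSON-serializable dict with exact, +/-1-day, three-grade
    and two-grade accuracies plus all confusion matrices; regenerating
    from the same inputs is byte-identical.
    """
    class_days = fused.confusion.class_days
    groupings = groupings or default_groupings(class_days)
    report = {
        "class_days": [d.item() if hasattr(d, "item") else d
                       for d in class_days],
        "modes": {},
        "fused": {},
    }
    for mode, cm in sorted(mode_results.items()):
        report["modes"][mode] = _metrics(cm, groupings)
        report["modes"][mode]["confusion"] = cm.counts.tolist()
    report["fused"] = _metrics(fused.confusion, groupings)
    report["fused"]["confusion"] = fused.confusion.counts.tolist()
    report["fused"]["tie_breaks"] = int(fused.tie_break_used.sum())
    return report


def report_markdown(report: dict) -> str:
    """Render a fillet report as a small markdown table."""
    lines = ["# Freshness classification report", "",
             f"Day classes: {report['class_days']}", "",
             "| source | exact | ±1 day | 3-grade | 2-grade |",
             "|---|---|---|---|---|"]
    rows = list(report["modes"].items()) + [("fused", report["fused"])]
    for name, m in rows:
        lines.append(
            f"| {name} | {m['exact_accuracy']:.3f} "
            f"| {m['tolerance_1day_accuracy']:.3f} "
            f"| {m['three_grade_accuracy']:.3f} "
            f"| {m['two_grade_accuracy']:.3f} |"
        )
    return "\n".join(lines) + "\n"
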
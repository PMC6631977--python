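"""Per-sample diagnosis from replicate predictions, and the clinical metrics.

Each tissue sample is measured at three locations, giving three spectra and
three per-spectrum predictions.  The diagnostic call for the sample uses an
OR rule with mutant as the positive class: the sample is called wild type
only when *all* replicate predictions are wild type, otherwise mutant.  The
rule trades specificity for sensitivity on purpose — missing a mutant is the
costly error in a screening setting.

Metrics (mutant = positive): sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/total.  Display values are rounded half-up to one decimal;
full precision is kept internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Sequence

from .errors import DataError, LabelError, ShapeError
from .spectra_io import Label


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class DiagnosticReport:
    """Sensitivity/specificity/accuracy (percent, full precision) + counts."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    counts: ConfusionCounts

    def rounded(self) -> tuple[float, float, float]:
        """One-decimal display values (half-up)."""
        return (
            round_half_up(self.sensitivity_pct),
            round_half_up(self.specificity_pct),
            round_half_up(self.accuracy_pct),
        )


def aggregate_sample(predictions: Sequence[Hashable]) -> Label:
    """OR-rule diagnosis over one sample's replicate predictions.

    Wild type iff every replicate prediction is wild type; mutant as soon as
    any replicate is called mutant.
    """
    preds = [Label(p) for p in predictions]
    if not preds:
        raise DataError("cannot diagnose a sample with no replicate predictions")
    if len(preds) != 3:
        warnings.warn(
            f"sample diagnosed from {len(preds)} replicate(s) instead of 3",
            stacklevel=2,
        )
    if any(p is Label.UNKNOWN for p in preds):
        raise LabelError("replicate predictions must be mutant or wild_type")
    return Label.WILD_TYPE if all(p is Label.WILD_TYPE for p in preds) else Label.MUTANT


def diagnose_samples(
    sample_ids: Sequence[str],
    predictions: Sequence[Hashable],
    true_labels: Sequence[Hashable],
) -> tuple[list[str], list[Label], list[Label]]:
    """Group per-spectrum predictions by sample and apply the OR rule.

    Returns ``(sample_ids, true, diagnosed)`` in first-appearance order.
    """
    if not (len(sample_ids) == len(predictions) == len(true_labels)):
        raise ShapeError("sample_ids, predictions and true_labels must align")
    grouped: dict[str, list[Hashable]] = {}
    truth: dict[str, Label] = {}
    for sid, pred, lab in zip(sample_ids, predictions, true_labels):
        grouped.setdefault(sid, []).append(pred)
        lab = Label(lab)
        if truth.setdefault(sid, lab) is not lab:
            raise LabelError(f"sample {sid!r} has inconsistent reference labels")
    ids = list(grouped)
    return ids, [truth[s] for s in ids], [aggregate_sample(grouped[s]) for s in ids]


def confusion(
    true_labels: Iterable[Hashable], diagnosed: Iterable[Hashable]
) -> ConfusionCounts:
    """Tally confusion counts with mutant as the positive class."""
    true_list = [Label(t) for t in true_labels]
    diag_list = [Label(d) for d in diagnosed]
    if len(true_list) != len(diag_list):
        raise ShapeError(
            f"{len(true_list)} true labels vs {len(diag_list)} diagnoses"
        )
    allowed = (Label.MUTANT, Label.WILD_TYPE)
    if any(t not in allowed for t in true_list) or any(d not in allowed for d in diag_list):
        raise LabelError("labels must be mutant or wild_type")
    tp = sum(t is Label.MUTANT and d is Label.MUTANT for t, d in zip(true_list, diag_list))
    fn = sum(t is Label.MUTANT and d is Label.WILD_TYPE for t, d in zip(true_list, diag_list))
    tn = sum(t is Label.WILD_TYPE and d is Label.WILD_TYPE for t, d in zip(true_list, diag_list))
    fp = sum(t is Label.WILD_TYPE and d is Label.MUTANT for t, d in zip(true_list, diag_list))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


class UndefinedMetricError(DataError):
    """A metric's denominator is zero (no positives / no negatives)."""


def metrics(counts: ConfusionCounts) -> DiagnosticReport:
    """Sensitivity/specificity/accuracy from confusion counts (percent)."""
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    if counts.TN + counts.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined: no samples")
    return DiagnosticReport(
        sensitivity_pct=100.0 * counts.TP / (counts.TP + counts.FN),
        specificity_pct=100.0 * counts.TN / (counts.TN + counts.FP),
        accuracy_pct=100.0 * (counts.TP + counts.TN) / counts.total,
        counts=counts,
    )


def diagnostic_report(
    sample_ids: Sequence[str],
    predictions: Sequence[Hashable],
    true_labels: Sequence[Hashable],
) -> DiagnosticReport:
    """Per-spectrum predictions -> OR-rule sample diagnoses -> metrics."""
    _, truth, diagnosed = diagnose_samples(sample_ids, predictions, true_labels)
    return metrics(confusion(truth, diagnosed))
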
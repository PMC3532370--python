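"""Leave-one-out validation, confusion metrics, and CS calibration.

Performance is reported per localization class as one-vs-rest confusion
metrics (precision, sensitivity, specificity, Matthews correlation
coefficient) over the top-1 calls of single-labelled sequences, plus an
overall accuracy in which multi-labelled sequences are credited by the
any-match rule: a prediction is correct if any of the true localization
classes appears in the call (including the second class of a dual
"X/Y" call).

The confidence score (CS) is benchmarked by binning predictions into
deciles [0,10), [10,20), ..., [90,100] and tabulating per-bin and
cumulative ("CS >= edge") data share and accuracy — the standard
reliability table for this classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .classifier import NgramModel, Prediction
from .errors import InsufficientData
from .sequences import SequenceRecord, SpeciesProfile, get_profile

__all__ = [
    "ClassMetrics",
    "CalibrationBin",
    "CalibrationTable",
    "EvaluationReport",
    "is_correct",
    "benchmark_cs",
    "evaluate_predictions",
    "loo_validate",
]


def is_correct(prediction: Prediction, labels: Iterable[str]) -> bool:
    """Any-match correctness rule for (possibly multi-labelled) truth.

    True iff the top-ranked class is a true label, or the call is a dual
    "X/Y" and either component is a true label.
    """
    labels = set(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    return any(part in labels for part in prediction.call.split("/"))


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest confusion counts and derived metrics for one class.

    All 0/0 cases evaluate to 0 (this matters for very small classes).
    """

    code: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    mcc: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        object.__setattr__(self, "precision", _safe_div(tp, tp + fp))
        object.__setattr__(self, "sensitivity", _safe_div(tp, tp + fn))
        object.__setattr__(self, "specificity", _safe_div(tn, tn + fp))
        denom = math.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        object.__setattr__(self, "mcc", _safe_div(tp * tn - fp * fn, denom))

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CalibrationBin:
    """One CS decile: members with lower <= CS < lower+10 (last bin closed).

    ``pct_accuracy`` is ``None`` for an empty bin (rendered as "-").
    Cumulative fields cover all predictions with CS >= ``lower``.
    """

    lower: int
    count: int
    n_correct: int
    pct_of_dataset: float
    pct_accuracy: float | None
    cum_count: int
    cum_correct: int
    cumulative_pct_of_data: float
    cumulative_pct_accuracy: float | None

    @property
    def upper(self) -> int:
        return self.lower + 10


@dataclass(frozen=True)
class CalibrationTable:
    """Ten CS-decile rows plus the dataset size they were computed from."""

    n_total: int
    bins: tuple[CalibrationBin, ...]

    def bin_at(self, lower: int) -> CalibrationBin:
        return self.bins[lower // 10]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cs_lower": [b.lower for b in self.bins],
                "pct_of_dataset": [b.pct_of_dataset for b in self.bins],
                "pct_accuracy": [b.pct_accuracy for b in self.bins],
                "cumulative_pct_of_data": [b.cumulative_pct_of_data for b in self.bins],
                "cumulative_pct_accuracy": [
                    b.cumulative_pct_accuracy for b in self.bins
                ],
            }
        )

    def render(self, label: str = "") -> str:
        """Tab-separated reliability table in the published layout.

        Column headings run 0..90; the per-bin statistics of decile
        [e, e+10) sit under the column labelled e+10 (the bin's upper
        edge), and the cumulative statistics under column c cover
        CS >= max(0, c-10); hence column 0 has no per-bin entries and its
        cumulative row repeats the whole-dataset figures.
        """
        cols = list(range(0, 100, 10))

        def fmt(v: float | None) -> str:
            return "-" if v is None else f"{v:.1f}"

        per_pct, per_acc, cum_data, cum_acc = ["-"], ["-"], [], []
        for c in cols:
            if c > 0:
                b = self.bin_at(c - 10)
                per_pct.append(fmt(b.pct_of_dataset if b.count else None))
                per_acc.append(fmt(b.pct_accuracy))
            b = self.bin_at(max(0, c - 10))
            cum_data.append(fmt(b.cumulative_pct_of_data))
            cum_acc.append(fmt(b.cumulative_pct_accuracy))
        head = "\t".join([label, ""] + [str(c) for c in cols])
        rows = [
            "\t".join(["", "% of dataset"] + per_pct),
            "\t".join(["", "% accuracy"] + per_acc),
            "\t".join(["", "Cumulative % of data"] + cum_data),
            "\t".join(["", "Cumulative % accuracy"] + cum_acc),
        ]
        return "\n".join([head] + rows) + "\n"


def benchmark_cs(
    predictions: Sequence[tuple[Prediction, Iterable[str]]]
) -> CalibrationTable:
    """Bin (prediction, true-labels) pairs by CS decile.

    Accuracy within each bin uses the any-match rule of
    :func:`is_correct`.  CS = 100 falls in the closed last bin [90, 100].
    """
    if not predictions:
        raise ValueError("predictions must be non-empty")
    counts = [0] * 10
    corrects = [0] * 10
    for pred, labels in predictions:
        idx = min(int(pred.cs // 10), 9)
        counts[idx] += 1
        if is_correct(pred, labels):
            corrects[idx] += 1
    total = sum(counts)
    bins: list[CalibrationBin] = []
    cum_count = cum_correct = 0
    suffix: list[tuple[int, int]] = [(0, 0)] * 10
    for i in range(9, -1, -1):
        cum_count += counts[i]
        cum_correct += corrects[i]
        suffix[i] = (cum_count, cum_correct)
    for i in range(10):
        cc, ccor = suffix[i]
        bins.append(
            CalibrationBin(
                lower=10 * i,
                count=counts[i],
                n_correct=corrects[i],
                pct_of_dataset=100.0 * counts[i] / total,
                pct_accuracy=(100.0 * corrects[i] / counts[i]) if counts[i] else None,
                cum_count=cc,
                cum_correct=ccor,
                cumulative_pct_of_data=100.0 * cc / total,
                cumulative_pct_accuracy=(100.0 * ccor / cc) if cc else None,
            )
        )
    return CalibrationTable(n_total=total, bins=tuple(bins))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class metrics, overall accuracy and the CS calibration table."""

    per_class: tuple[ClassMetrics, ...]
    overall_accuracy: float
    n_evaluated: int
    n_correct: int
    cs_table: CalibrationTable

    def metrics_for(self, code: str) -> ClassMetrics:
        for m in self.per_class:
            if m.code == code:
                return m
        raise KeyError(code)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [m.code for m in self.per_class],
                "tp": [m.tp for m in self.per_class],
                "fp": [m.fp for m in self.per_class],
                "fn": [m.fn for m in self.per_class],
                "tn": [m.tn for m in self.per_class],
                "precision": [m.precision for m in self.per_class],
                "sensitivity": [m.sensitivity for m in self.per_class],
                "specificity": [m.specificity for m in self.per_class],
                "mcc": [m.mcc for m in self.per_class],
            }
        )

    def render_table(self) -> str:
        """Tab-separated class-wise performance table."""
        lines = ["Code\tPrec.\tSens.\tSpec.\tMCC"]
        for m in self.per_class:
            lines.append(
                f"{m.code}\t{m.precision:.3f}\t{m.sensitivity:.3f}"
                f"\t{m.specificity:.3f}\t{m.mcc:.3f}"
            )
        lines.append(f"% Overall accuracy\t{self.overall_accuracy:.2f}%")
        return "\n".join(lines) + "\n"

    def render_machine(self) -> str:
        """One ``class<TAB>metric<TAB>value`` line per metric."""
        lines = []
        for m in self.per_class:
            for name in ("tp", "fp", "fn", "tn"):
                lines.append(f"{m.code}\t{name}\t{getattr(m, name)}")
            for name in ("precision", "sensitivity", "specificity", "mcc"):
                lines.append(f"{m.code}\t{name}\t{getattr(m, name)!r}")
        lines.append(f"OVERALL\tn_evaluated\t{self.n_evaluated}")
        lines.append(f"OVERALL\tn_correct\t{self.n_correct}")
        lines.append(f"OVERALL\taccuracy\t{self.overall_accuracy!r}")
        return "\n".join(lines) + "\n"


def evaluate_predictions(
    pairs: Sequence[tuple[Prediction, tuple[str, ...]]],
    profile: SpeciesProfile,
    include_multilabel_per_class: bool = False,
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from scored pairs.

    Per-class one-vs-rest confusion is computed over top-1 calls of
    single-labelled records; multi-labelled records count toward overall
    accuracy only (any-match rule), unless
    ``include_multilabel_per_class`` is set, in which case a
    multi-labelled record is a TP for each of its true classes when
    predicted there and an FN for each otherwise.
    """
    if not pairs:
        raise ValueError("no predictions to evaluate")
    n_correct = sum(is_correct(pred, labels) for pred, labels in pairs)
    n_evaluated = len(pairs)
    if include_multilabel_per_class:
        ovr = [(p.top, labels) for p, labels in pairs]
    else:
        ovr = [(p.top, labels) for p, labels in pairs if len(labels) == 1]
    metrics = []
    for code in profile.class_codes:
        tp = fp = fn = tn = 0
        for top, labels in ovr:
            truth = code in labels
            predicted = top == code
            if truth and predicted:
                tp += 1
            elif truth:
                fn += 1
            elif predicted:
                fp += 1
            else:
                tn += 1
        metrics.append(ClassMetrics(code, tp, fp, fn, tn))
    return EvaluationReport(
        per_class=tuple(metrics),
        overall_accuracy=100.0 * n_correct / n_evaluated,
        n_evaluated=n_evaluated,
        n_correct=n_correct,
        cs_table=benchmark_cs(pairs),
    )


def loo_validate(
    records: Sequence[SequenceRecord],
    profile: SpeciesProfile | str,
    n: int | None = None,
    alpha: float = 1.0,
    priors: str = "empirical",
    mlcs_threshold: float = 60.0,
    include_multilabel_per_class: bool = False,
) -> EvaluationReport:
    """Leave-one-out validation via the count decrement trick.

    The model is trained once; each record is then removed, scored, and
    restored, which is exactly equivalent to retraining on the remaining
    records with the vocabulary size held fixed.  Deterministic:
    identical inputs give identical reports.

    Raises :class:`InsufficientData` if any class present in the records
    has fewer than two training sequences (it would empty under LOO).
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    model = NgramModel.train(
        records, profile, n=n, alpha=alpha, priors=priors, mlcs_threshold=mlcs_threshold
    )
    skipped_ids = {rid for rid, _ in model.training_skipped}
    used = [r for r in records if r.id not in skipped_ids]
    thin = [
        c for c in profile.class_codes if 0 < model.class_seq_counts[c] < 2
    ]
    if thin:
        raise InsufficientData(
            f"classes with a single training sequence would empty under "
            f"leave-one-out: {', '.join(thin)}"
        )
    if len(used) < 2:
        raise InsufficientData("need at least two usable records for leave-one-out")
    pairs: list[tuple[Prediction, tuple[str, ...]]] = []
    for rec in used:
        model.loo_remove(rec)
        try:
            pred = model.score(rec.sequence, seq_id=rec.id)
        finally:
            model.loo_restore(rec)
        pairs.append((pred, rec.labels))
    return evaluate_predictions(
        pairs, profile, include_multilabel_per_class=include_multilabel_per_class
    )
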
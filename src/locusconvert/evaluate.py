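"""Conversion-accuracy evaluation against a truth mapping.

Each evaluated query *x* has a truth target set *Z(x)* (what the authority
annotates, possibly empty) and a predicted set *Y(x)* (what the converter
returned).  The four outcomes partition all (Z, Y) pairs:

- **TP**: Z != {} and Z is a subset of Y — the conversion recovered every
  annotated target (extra predictions do not penalize here);
- **FP**: a wrong or unexpected conversion — Z != {} and Y != {} but Z is not
  a subset of Y, or Z == {} while the tool predicted something;
- **FN**: Z != {} and Y == {} — an annotated query the tool failed to convert;
- **TN**: Z == {} and Y == {} — correctly converted to nothing.

Derived metrics (all percentages):
ACC = 100*(TP+TN)/(TP+TN+FP+FN), TPR = 100*TP/(TP+FN),
FPR = 100*FP/(FP+TN), FDR = 100*FP/(TP+FP), F1 = 100*2TP/(2TP+FP+FN).
A metric with a zero denominator is reported as undefined (None), never
silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

from .convert import ConversionReport

METRIC_NAMES = ("TPR", "FPR", "ACC", "FDR", "F1")


def classify(Z: set, Y: set) -> str:
    """Label one (truth, predicted) pair as TP, FP, FN or TN."""
    if Z:
        if not Y:
            return "FN"
        return "TP" if Z <= Y else "FP"
    return "FP" if Y else "TN"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def total_mapped(self) -> int:
        """Queries with a non-empty predicted set (TP + FP)."""
        return self.tp + self.fp


def accuracy(c: ConfusionCounts) -> float:
    """Percent accuracy, 100*(TP+TN)/(TP+TN+FP+FN)."""
    if c.total == 0:
        raise ZeroDivisionError("no evaluated queries")
    return 100.0 * (c.tp + c.tn) / c.total


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def derived_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """TPR/FPR/ACC/FDR/F1 in full precision; None where undefined."""
    return {
        "TPR": _ratio(c.tp, c.tp + c.fn),
        "FPR": _ratio(c.fp, c.fp + c.tn),
        "ACC": _ratio(c.tp + c.tn, c.total),
        "FDR": _ratio(c.fp, c.tp + c.fp),
        "F1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rounded_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Reporting form of :func:`derived_metrics`: 2 decimals, half-up."""
    return {
        k: (None if v is None else round_half_up(v, 2))
        for k, v in derived_metrics(c).items()
    }


def make_prefix_filter(
    keep_prefixes: Sequence[str] = ("NM_", "NR_"),
    drop_prefixes: Sequence[str] = ("X",),
) -> Callable[[set[str]], set[str]]:
    """Identifier-class filter applied to predicted sets before scoring.

    The default keeps curated mRNA/RNA accessions (NM_/NR_) and drops
    computationally predicted ones (X*), the convention used when comparing
    converters that segregate accession classes differently.
    Drop takes precedence over keep.
    """

    def _filter(ids: set[str]) -> set[str]:
        out = set()
        for i in ids:
            if any(i.startswith(p) for p in drop_prefixes):
                continue
            if keep_prefixes and not any(i.startswith(p) for p in keep_prefixes):
                continue
            out.add(i)
        return out

    return _filter


@dataclass
class EvaluationResult:
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    labels: dict[str, str]  # query id -> TP/FP/FN/TN


def evaluate_sets(
    truth: Mapping[str, set[str]],
    predicted: Mapping[str, set[str]],
    evaluated_ids: Iterable[str],
    prediction_filter: Callable[[set[str]], set[str]] | None = None,
) -> EvaluationResult:
    """Tally the confusion counts of predicted sets against a truth mapping."""
    tally = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    labels: dict[str, str] = {}
    for qid in evaluated_ids:
        if qid not in truth:
            raise KeyError(f"{qid!r} has no truth entry")
        Z = set(truth[qid])
        Y = set(predicted.get(qid, set()))
        if prediction_filter is not None:
            Y = prediction_filter(Y)
        lab = classify(Z, Y)
        labels[qid] = lab
        tally[lab] += 1
    counts = ConfusionCounts(tally["TP"], tally["FP"], tally["FN"], tally["TN"])
    return EvaluationResult(counts, derived_metrics(counts), labels)


def evaluate_conversion(
    report: ConversionReport,
    truth: Mapping[str, set[str]],
    evaluated_ids: Iterable[str] | None = None,
    prediction_filter: Callable[[set[str]], set[str]] | None = None,
) -> EvaluationResult:
    """Score a conversion report: Y(x) = subject ids reported for x."""
    predicted = report.predicted_sets()
    if evaluated_ids is None:
        evaluated_ids = list(predicted)
    return evaluate_sets(truth, predicted, evaluated_ids, prediction_filter)


def corrupt_truth(
    truth: Mapping[str, set[str]],
    fraction: float,
    seed: int,
    bogus_id: str = "__CORRUPTED__",
) -> dict[str, set[str]]:
    """Adversarially perturb a known fraction of truth entries.

    A corrupted entry gains an unsatisfiable required target, so a query the
    converter previously got fully right flips from TP to FP — each corrupted
    entry lowers accuracy by exactly one evaluated query.  Used to check that
    the evaluation framework's accuracy scale responds linearly.
    """
    import random

    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    ids = sorted(truth)
    n_corrupt = round(fraction * len(ids))
    chosen = set(random.Random(seed).sample(ids, n_corrupt))
    return {
        qid: (set(t) | {bogus_id}) if qid in chosen else set(t)
        for qid, t in truth.items()
    }
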
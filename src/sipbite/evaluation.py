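"""Evaluation: confusion matrices, P/R/F1, sensitivity, specificity, FP/h.

Eating is scored on the 1-min grid and drinking (plus the 3-class overall
report) on the 10-s grid; minute-level eating labels are broadcast onto
their six 10-s units for the overall matrix.  Drink events are also
matched one-to-one against the ground truth with a time tolerance, which
feeds the event-level FP/h figure.

All 0/0 metric ratios are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CLASSES, LabelTrack, rasterize_labels


@dataclass
class EvalReport:
    """Scores of one prediction run against ground truth."""

    classes: tuple[str, ...]
    matrix: np.ndarray                       # rows = truth, cols = prediction
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    weighted_precision: float = 0.0
    weighted_recall: float = 0.0
    weighted_f1: float = 0.0
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    fp_per_hour: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["confusion matrix (rows=truth, cols=prediction):"]
        head = "".join(f"{c:>10}" for c in self.classes)
        lines.append(" " * 8 + head)
        for i, c in enumerate(self.classes):
            row = "".join(f"{int(v):>10}" for v in self.matrix[i])
            lines.append(f"{c:>8}{row}")
        lines.append("")
        lines.append(f"{'class':>8}{'prec':>8}{'rec':>8}{'f1':>8}{'support':>9}")
        for c in self.classes:
            lines.append(
                f"{c:>8}{self.precision[c]:>8.2f}{self.recall[c]:>8.2f}"
                f"{self.f1[c]:>8.2f}{self.support[c]:>9}"
            )
        lines.append(
            f"{'wavg':>8}{self.weighted_precision:>8.2f}"
            f"{self.weighted_recall:>8.2f}{self.weighted_f1:>8.2f}"
            f"{sum(self.support.values()):>9}"
        )
        for c, v in self.fp_per_hour.items():
            lines.append(f"FP/h ({c}): {v:.2f}")
        return "\n".join(lines)


def confusion(truth, pred, classes=CLASSES) -> np.ndarray:
    """Count (truth, prediction) pairs; rows = truth, cols = prediction."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside classes: {t!r}/{p!r}")
        M[index[t], index[p]] += 1
    return M


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def prf(matrix: np.ndarray, classes=CLASSES) -> dict:
    """Per-class and support-weighted precision/recall/F1 from a matrix."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    diag = np.diag(M)
    col = M.sum(axis=0)
    row = M.sum(axis=1)
    precision = {c: _safe_div(diag[i], col[i]) for i, c in enumerate(classes)}
    recall = {c: _safe_div(diag[i], row[i]) for i, c in enumerate(classes)}
    f1 = {
        c: _safe_div(2 * precision[c] * recall[c], precision[c] + recall[c])
        for c in classes
    }
    total = row.sum()
    weighted = {
        name: _safe_div(sum(row[i] * d[c] for i, c in enumerate(classes)), total)
        for name, d in (("precision", precision), ("recall", recall), ("f1", f1))
    }
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": {c: int(row[i]) for i, c in enumerate(classes)},
        "weighted_precision": weighted["precision"],
        "weighted_recall": weighted["recall"],
        "weighted_f1": weighted["f1"],
    }


def weighted_f1_from_scores(f1_scores, supports) -> float:
    """Support-weighted mean of per-class F1 values."""
    f1_scores = np.asarray(f1_scores, dtype=float)
    supports = np.asarray(supports, dtype=float)
    return float(_safe_div((f1_scores * supports).sum(), supports.sum()))


def sens_spec_fph(
    truth, pred, positive_class: str, hours: float
) -> tuple[float, float, float]:
    """Sensitivity, specificity and false positives per hour.

    Units are whatever grid the vectors live on (minutes for eating,
    10-s units for drinking); FP/h counts false-positive units per hour
    of acquisition.
    """
    if not hours > 0:
        raise ValueError("hours must be > 0")
    t = np.asarray(list(truth)) == positive_class
    p = np.asarray(list(pred)) == positive_class
    tp = int((t & p).sum())
    fn = int((t & ~p).sum())
    fp = int((~t & p).sum())
    tn = int((~t & ~p).sum())
    return (
        _safe_div(tp, tp + fn),
        _safe_div(tn, tn + fp),
        fp / hours,
    )


def match_drink_events(
    pred_events, true_events, tol_s: float = 10.0
) -> tuple[int, int, int]:
    """Greedy one-to-one event matching with a time tolerance.

    Events are ``(start_s, end_s)`` pairs (extra fields ignored), sorted
    in time.  Processing predictions in time order, a prediction whose
    gap to some unmatched true event is at most ``tol_s`` (0 when the
    intervals overlap) is a TP and consumes the closest such truth;
    leftover predictions are FP, leftover truths FN.
    """
    preds = sorted((e[0], e[1]) for e in pred_events)
    truths = sorted((e[0], e[1]) for e in true_events)
    matched = [False] * len(truths)
    tp = fp = 0
    for ps, pe in preds:
        best = None
        best_gap = None
        for j, (ts, te) in enumerate(truths):
            if matched[j]:
                continue
            gap = max(0.0, max(ps, ts) - min(pe, te))
            if gap <= tol_s and (best_gap is None or gap < best_gap):
                best, best_gap = j, gap
        if best is not None:
            matched[best] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    return tp, fp, fn


def evaluate_day(
    truth_track: LabelTrack,
    fused_units: list[str],
    drink_events,
    t0: float,
    duration_s: float,
    drink_match_tol_s: float = 10.0,
) -> EvalReport:
    """Score one day's fused predictions against a ground-truth track.

    The 3-class confusion matrix lives on the 10-s grid; eating
    sensitivity/specificity/FP-minutes-per-hour are computed on the 1-min
    grid; drinking FP/h comes from tolerance-matched events.
    """
    n_units = len(fused_units)
    truth_units = rasterize_labels(truth_track, t0, 10.0, n_units)
    M = confusion(truth_units, fused_units)
    scores = prf(M)
    hours = duration_s / 3600.0

    # minute grids: an eating minute is one with >3 of its 6 units eating
    def to_minutes(units):
        flags = np.asarray([u == "eat" for u in units])
        n_min = int(np.ceil(len(flags) / 6))
        return [
            "eat" if flags[6 * m : 6 * m + 6].sum() > 3 else "other"
            for m in range(n_min)
        ]

    eat_sens, eat_spec, eat_fph = sens_spec_fph(
        to_minutes(truth_units), to_minutes(fused_units), "eat", hours
    )
    true_drinks = [(iv.start_s - t0, iv.end_s - t0)
                   for iv in truth_track.of_label("drink")]
    tp, fp_ev, fn = match_drink_events(drink_events, true_drinks,
                                       drink_match_tol_s)
    d_sens = _safe_div(tp, tp + fn)
    du = np.asarray(truth_units) == "drink"
    pu = np.asarray(fused_units) == "drink"
    d_spec = _safe_div(int((~du & ~pu).sum()), int((~du).sum()))
    return EvalReport(
        classes=CLASSES,
        matrix=M,
        precision=scores["precision"],
        recall=scores["recall"],
        f1=scores["f1"],
        support=scores["support"],
        weighted_precision=scores["weighted_precision"],
        weighted_recall=scores["weighted_recall"],
        weighted_f1=scores["weighted_f1"],
        sensitivity={"eat": eat_sens, "drink": d_sens},
        specificity={"eat": eat_spec, "drink": d_spec},
        fp_per_hour={"eat": eat_fph, "drink": fp_ev / hours},
    )
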
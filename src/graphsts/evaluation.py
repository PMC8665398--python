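"""Pearson-correlation evaluation, per-category breakdown and data splits.

The similarity task is scored by the Pearson product-moment correlation
between predicted and gold scores, overall and within each annotated
category.  Correlations that are undefined — fewer than two points, or a
constant vector — are reported as missing rather than coerced to zero, so a
degenerate subset can never masquerade as "no correlation".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .augmentation import SentenceRecord
from .errors import InputError

__all__ = ["UndefinedCorrelationError", "EvalReport", "pearson", "evaluate",
           "split_dataset"]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (constant input or n < 2)."""


@dataclass
class EvalReport:
    overall_r: float | None
    n_overall: int
    per_category_r: dict[str, float | None] = field(default_factory=dict)
    per_category_n: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "overall_r": self.overall_r,
            "n_overall": self.n_overall,
            "per_category_r": self.per_category_r,
            "per_category_n": self.per_category_n,
        }, indent=2, sort_keys=True)

    def to_table(self) -> str:
        rows = [("all", self.overall_r, self.n_overall)]
        for cat in sorted(self.per_category_n):
            rows.append((cat, self.per_category_r.get(cat),
                         self.per_category_n[cat]))
        width = max(len(r[0]) for r in rows)
        lines = [f"{'subset':<{width}}  {'r':>8}  {'n':>6}"]
        for name, r, n in rows:
            r_s = "missing" if r is None else f"{r:.4f}"
            lines.append(f"{name:<{width}}  {r_s:>8}  {n:>6}")
        return "\n".join(lines)


def pearson(predictions, golds) -> float:
    """Product-moment correlation; raises
    :class:`UndefinedCorrelationError` for n < 2 or a constant vector."""
    x = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(golds, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("prediction and gold vectors must be equal-length "
                         "1-d arrays")
    if len(x) < 2:
        raise UndefinedCorrelationError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    return float(stats.pearsonr(x, y).statistic)


def evaluate(predictions, dataset: list[SentenceRecord]) -> EvalReport:
    """Overall and per-category Pearson r of predictions against gold
    scores.  Every prediction must match a dataset record id; categories
    whose correlation is undefined are reported as missing (None)."""
    by_id = {r.record_id: r for r in dataset}
    unmatched = [p.record_id for p in predictions if p.record_id not in by_id]
    if unmatched:
        raise InputError("predictions with no matching record: "
                         + ", ".join(sorted(unmatched)))
    pred_scores, gold_scores, categories = [], [], []
    for p in predictions:
        record = by_id[p.record_id]
        if record.score is None:
            raise InputError(f"record {record.record_id} has no gold score")
        pred_scores.append(p.score)
        gold_scores.append(record.score)
        categories.append(record.category)
    pred_arr = np.asarray(pred_scores)
    gold_arr = np.asarray(gold_scores)

    def safe_pearson(x, y):
        try:
            return pearson(x, y)
        except UndefinedCorrelationError:
            return None

    report = EvalReport(overall_r=safe_pearson(pred_arr, gold_arr),
                        n_overall=len(pred_arr))
    for cat in sorted({c for c in categories if c is not None}):
        idx = [i for i, c in enumerate(categories) if c == cat]
        report.per_category_n[cat] = len(idx)
        report.per_category_r[cat] = safe_pearson(pred_arr[idx],
                                                  gold_arr[idx])
    return report


def split_dataset(dataset: list[SentenceRecord], train_n: int, val_n: int,
                  seed: int) -> tuple[list[SentenceRecord],
                                      list[SentenceRecord]]:
    """Seeded shuffle then prefix split into disjoint, exhaustive parts."""
    if train_n + val_n != len(dataset):
        raise InputError(f"train_n + val_n = {train_n + val_n} does not "
                         f"equal dataset size {len(dataset)}")
    order = np.random.default_rng(seed).permutation(len(dataset))
    shuffled = [dataset[i] for i in order]
    return shuffled[:train_n], shuffled[train_n:]
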
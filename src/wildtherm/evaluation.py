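"""Confusion-count accumulation and the presence-classification metrics.

Detection is scored per frame against a ground-truth presence table:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and
accuracy = (TP+TN)/(TP+TN+FP+FN), each reported as a percentage rounded to
two decimals; the average per-frame execution time completes the
comparison-table columns.  Zero denominators report as undefined (None),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError
from .pipelines import DetectionResult


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sensitivity_pct: float | None
    specificity_pct: float | None
    accuracy_pct: float | None
    avg_time_s: float | None
    n_frames: int
    # exact rationals behind the rounded percentages
    raw_sensitivity: Fraction | None = None
    raw_specificity: Fraction | None = None
    raw_accuracy: Fraction | None = None


def read_truth(path) -> dict[str, bool]:
    """Read a ground-truth CSV (``frame_id,has_animal`` with optional boxes)."""
    df = pd.read_csv(path, dtype={"frame_id": str})
    if "frame_id" not in df.columns or "has_animal" not in df.columns:
        raise DataError("truth CSV must have columns frame_id,has_animal")
    return {row.frame_id: bool(int(row.has_animal)) for row in df.itertuples()}


def accumulate(
    results: Iterable[DetectionResult], truth: Mapping[str, bool]
) -> ConfusionCounts:
    """Tally per-frame predictions against ground truth.

    Results flagged ``scored=False`` (a motion run's first frame) are
    skipped; every scored frame must have a truth row.
    """
    c = ConfusionCounts()
    for res in results:
        if not res.scored:
            continue
        if res.frame_id not in truth:
            raise DataError(f"no ground-truth row for frame {res.frame_id!r}")
        actual = truth[res.frame_id]
        if res.present and actual:
            c.tp += 1
        elif res.present and not actual:
            c.fp += 1
        elif not res.present and actual:
            c.fn += 1
        else:
            c.tn += 1
    return c


def _pct(num: int, den: int) -> tuple[float | None, Fraction | None]:
    if den == 0:
        return None, None
    frac = Fraction(num, den)
    return round(float(100 * frac), 2), frac


def metrics(c: ConfusionCounts, times: Iterable[float] = ()) -> MetricsReport:
    """Compute the comparison-table metrics from confusion counts."""
    sens, raw_sens = _pct(c.tp, c.tp + c.fn)
    spec, raw_spec = _pct(c.tn, c.tn + c.fp)
    acc, raw_acc = _pct(c.tp + c.tn, c.total)
    times = list(times)
    avg_t = round(sum(times) / len(times), 6) if times else None
    return MetricsReport(
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=acc,
        avg_time_s=avg_t,
        n_frames=c.total,
        raw_sensitivity=raw_sens,
        raw_specificity=raw_spec,
        raw_accuracy=raw_acc,
    )


def compare_report(
    per_method: Mapping[str, tuple[ConfusionCounts, Iterable[float]]],
    include_time: bool = True,
) -> pd.DataFrame:
    """One row per method with the four comparison columns plus frame count."""
    rows = []
    for method, (counts, times) in per_method.items():
        rep = metrics(counts, times)
        row = {"method": method}
        if include_time:
            row["avg_time_s"] = rep.avg_time_s
        row.update(
            sensitivity_pct=rep.sensitivity_pct,
            specificity_pct=rep.specificity_pct,
            accuracy_pct=rep.accuracy_pct,
            n_frames=rep.n_frames,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(df: pd.DataFrame) -> str:
    """Human-readable rendering of a comparison table."""
    return df.to_string(index=False, na_rep="undefined")
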
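"""Confusion matrices and the standard performance-metric suite.

For a tool evaluated on a benchmark of positives (PVs) and negatives (BVs):

    sensitivity = TP / (TP + FN)          FNR = FN / (TP + FN) = 1 - Sen
    specificity = TN / (TN + FP)          FPR = FP / (TN + FP) = 1 - Spec
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

No-call variants are excluded from all four cells (complete-case per tool).
Rate metrics with a zero denominator are undefined (``None``); an MCC with
a zero denominator is reported as 0 and flagged degenerate, so degenerate
all-one-class predictors still sort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkSet
from .errors import ConfigError, DataError
from .registry import BENIGN, DELETERIOUS, NO_CALL
from .variant_model import VariantKey

log = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "fpr", "fnr", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """The four confusion-matrix cells (no-calls excluded)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")


@dataclass
class ToolPerformance:
    """Eq-style metric suite for one tool on one benchmark."""

    tool: str
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    fnr: float | None
    mcc: float | None
    mcc_degenerate: bool
    n_scored_pos: int
    n_scored_neg: int

    def metric(self, name: str) -> float | None:
        if name not in METRIC_NAMES:
            raise ConfigError(f"unknown metric {name!r}")
        return getattr(self, name)


def confusion_counts(
    calls: Mapping[VariantKey, int] | pd.Series, benchmark: BenchmarkSet
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for one tool's calls against a benchmark.

    ``calls`` maps every benchmark variant key to a call code
    (1 deleterious, 0 benign, -1 no-call). Keys missing from ``calls``
    raise, listing the offenders; no-calls are excluded from every cell.
    """
    if isinstance(calls, pd.Series):
        calls = calls.to_dict()
    missing = [k for k in benchmark.keys if k not in calls]
    if missing:
        raise DataError(
            f"{len(missing)} benchmark keys absent from call table, e.g. "
            + ", ".join(str(k) for k in sorted(missing)[:5])
        )
    tp = fp = tn = fn = 0
    for key in benchmark.positives:
        c = calls[key]
        if c == DELETERIOUS:
            tp += 1
        elif c == BENIGN:
            fn += 1
    for key in benchmark.negatives:
        c = calls[key]
        if c == DELETERIOUS:
            fp += 1
        elif c == BENIGN:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(c: ConfusionCounts, tool: str = "") -> ToolPerformance:
    """Compute the full metric suite from confusion counts."""
    sen = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    fpr = _ratio(c.fp, c.tn + c.fp)
    fnr = _ratio(c.fn, c.tp + c.fn)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    degenerate = denom == 0
    if degenerate:
        mcc: float | None = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return ToolPerformance(
        tool=tool,
        counts=c,
        sensitivity=sen,
        specificity=spec,
        fpr=fpr,
        fnr=fnr,
        mcc=mcc,
        mcc_degenerate=degenerate,
        n_scored_pos=c.tp + c.fn,
        n_scored_neg=c.tn + c.fp,
    )


def evaluate_all_tools(
    benchmark: BenchmarkSet,
    calls: pd.DataFrame,
    sort_by: str | None = "sensitivity",
) -> list[ToolPerformance]:
    """One :class:`ToolPerformance` per call-matrix column.

    Default ordering is descending sensitivity (undefined last), matching
    the published report layout; pass ``sort_by=None`` to keep column order.
    """
    if not benchmark.keys:
        log.warning("evaluate_all_tools: empty benchmark")
        return []
    perfs: list[ToolPerformance] = []
    # vectorized tally: one membership pass, then per-column bincounts
    keys = list(benchmark.keys)
    missing = [k for k in keys if k not in calls.index]
    if missing:
        raise DataError(f"{len(missing)} benchmark keys absent from call table")
    sub = calls.loc[keys]
    is_pos = np.array([k in benchmark.positives for k in keys])
    for tool in calls.columns:
        col = sub[tool].to_numpy()
        tp = int(((col == DELETERIOUS) & is_pos).sum())
        fn = int(((col == BENIGN) & is_pos).sum())
        fp = int(((col == DELETERIOUS) & ~is_pos).sum())
        tn = int(((col == BENIGN) & ~is_pos).sum())
        perf = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), tool=tool)
        if perf.n_scored_pos == 0 and perf.n_scored_neg == 0:
            log.warning("%s scored no benchmark variants", tool)
        perfs.append(perf)
    if sort_by is not None:
        perfs.sort(
            key=lambda p: (
                p.metric(sort_by) is None,
                -(p.metric(sort_by) or 0.0),
                p.tool,
            )
        )
    return perfs


def performance_table(perfs: Sequence[ToolPerformance], decimals: int = 2) -> pd.DataFrame:
    """Report-style table, one row per tool, metrics rounded."""
    rows = []
    for p in perfs:
        rows.append(
            {
                "tool": p.tool,
                **{
                    m: (round(v, decimals) if (v := p.metric(m)) is not None else float("nan"))
                    for m in METRIC_NAMES
                },
                "n_scored_pos": p.n_scored_pos,
                "n_scored_neg": p.n_scored_neg,
            }
        )
    return pd.DataFrame(rows)


def mean_row(
    perfs: Sequence[ToolPerformance] | Sequence[float | None], metric: str | None = None
) -> float:
    """Arithmetic mean of one metric across tools, undefined entries excluded.

    Accepts either :class:`ToolPerformance` rows plus a metric name, or a
    plain sequence of values (``None``/NaN skipped). Raises if nothing is
    defined.
    """
    if metric is not None and perfs and isinstance(perfs[0], ToolPerformance):
        values = [p.metric(metric) for p in perfs]  # type: ignore[union-attr]
    else:
        values = list(perfs)  # type: ignore[arg-type]
    usable = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    dropped = len(values) - len(usable)
    if dropped:
        log.info("mean_row: %d undefined entries excluded", dropped)
    if not usable:
        raise DataError("mean_row: all entries undefined")
    return float(np.mean(usable))


def paired_metric_test(
    a: Sequence[float | None],
    b: Sequence[float | None],
    method: str = "paired_t",
) -> tuple[float, float]:
    """Two-sided paired comparison of a metric across tools.

    Pairs with an undefined member are dropped (logged). ``paired_t`` is
    the default; ``wilcoxon`` gives the signed-rank alternative. Identical
    vectors return ``(0.0, 1.0)``.
    """
    if len(a) != len(b):
        raise ConfigError(f"length mismatch: {len(a)} vs {len(b)}")
    pairs = [
        (x, y)
        for x, y in zip(a, b)
        if x is not None and y is not None
        and not (isinstance(x, float) and math.isnan(x))
        and not (isinstance(y, float) and math.isnan(y))
    ]
    if len(pairs) < len(a):
        log.info("paired_metric_test: dropped %d incomplete pairs", len(a) - len(pairs))
    if len(pairs) < 2:
        raise DataError("paired test requires at least 2 usable pairs")
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    if np.allclose(xs, ys):
        return 0.0, 1.0
    if method == "paired_t":
        res = stats.ttest_rel(xs, ys)
    elif method == "wilcoxon":
        res = stats.wilcoxon(xs, ys)
    else:
        raise ConfigError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def per_capita_rate(n_variants: int, n_patients: int) -> float:
    """Variants per patient (e.g. PVs per sequenced case)."""
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if n_variants < 0:
        raise ConfigError("n_variants must be >= 0")
    return n_variants / n_patients


def fold_change(
    num_count: int,
    den_count: int,
    num_denom: int = 1,
    den_denom: int = 1,
    mode: str = "count_ratio",
) -> float | None:
    """Fold difference between two counts or two rates.

    ``count_ratio``: num_count / den_count. ``rate_ratio``:
    (num_count/num_denom) / (den_count/den_denom). ``larger_over_smaller``
    symmetrizes so the result is always >= 1. A zero denominator yields
    ``None`` with a warning.
    """
    if mode not in ("count_ratio", "rate_ratio", "larger_over_smaller"):
        raise ConfigError(f"unknown fold mode {mode!r}")
    if min(num_count, den_count) < 0 or min(num_denom, den_denom) < 1:
        raise ConfigError("counts must be >= 0 and denominators >= 1")
    if mode == "rate_ratio":
        num = num_count / num_denom
        den = den_count / den_denom
    else:
        num, den = float(num_count), float(den_count)
    if mode == "larger_over_smaller":
        num, den = max(num, den), min(num, den)
    if den == 0:
        log.warning("fold_change: zero denominator, undefined")
        return None
    return num / den
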
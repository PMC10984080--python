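"""Classifier evaluation: confusion metrics, ranking metrics, bootstrap CIs.

Point metrics follow the standard confusion-matrix definitions: sensitivity
(recall) TP/(TP+FN), specificity TN/(TN+FP), PPV (precision) TP/(TP+FP), NPV
TN/(TN+FN), accuracy, and F1 = 2·PPV·recall/(PPV+recall). A ratio with a zero
denominator is *undefined* (NaN), never silently 0.

AUROC is computed as the tie-corrected rank statistic — the probability that a
random case outscores a random control, counting ties half:

    AUROC = ( sum of case ranks − n1(n1+1)/2 ) / (n1 · n0)

with midranks for ties, which equals the all-pairs statistic
P(s_case > s_ctrl) + ½·P(tie). AUPRC is average precision (step integration of
the precision-recall curve).

Uncertainty comes from case-resampling bootstrap: ``(label, score)`` pairs are
resampled with replacement (default 1000 resamples), thresholded metrics are
recomputed per resample at the fixed threshold, and percentile 95% intervals
are reported alongside the resample mean and SD. Resamples that lose a class
are redrawn. Everything is seed-reproducible.

:func:`cohort_summary` renders "n (%)" cohort characteristic tables with
half-up rounding to one decimal and small-cell suppression for privacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = [
    "MetricsReport",
    "BootstrapSpec",
    "confusion_metrics",
    "auroc",
    "auprc",
    "bootstrap_metrics",
    "cohort_summary",
    "percent",
]

THRESHOLDED_METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1")
RANKING_METRICS = ("auroc", "auprc")
ALL_METRICS = THRESHOLDED_METRICS + RANKING_METRICS


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap resampling parameters (resample count, seed, CI level)."""

    n_resamples: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class MetricsReport:
    """Point metrics plus (optionally) bootstrap mean/SD/CI per metric.

    ``point`` maps metric name -> point estimate (NaN when undefined).
    ``mean``/``sd``/``ci_low``/``ci_high`` are filled by
    :func:`bootstrap_metrics`; ``n_undefined`` counts resamples where a metric
    was undefined and hence excluded from aggregation.
    """

    point: dict[str, float]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)
    n_resamples: int = 0

    def __getitem__(self, metric: str) -> float:
        return self.point[metric]

    def to_dict(self) -> dict:
        out: dict = {"point": dict(self.point)}
        if self.mean:
            out.update(
                mean=dict(self.mean),
                sd=dict(self.sd),
                ci_low=dict(self.ci_low),
                ci_high=dict(self.ci_high),
                n_undefined=dict(self.n_undefined),
                n_resamples=self.n_resamples,
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, v in self.point.items():
            row = {"metric": m, "estimate": v}
            if self.mean:
                row.update(
                    mean=self.mean.get(m, np.nan),
                    sd=self.sd.get(m, np.nan),
                    ci_low=self.ci_low.get(m, np.nan),
                    ci_high=self.ci_high.get(m, np.nan),
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Metric        estimate" + ("      mean        sd   95% CI" if self.mean else "")]
        for m, row in df.iterrows():
            s = f"{m:<12} {row['estimate']:9.4f}"
            if self.mean:
                s += (
                    f" {row['mean']:9.4f} {row['sd']:9.4f}"
                    f"   [{row['ci_low']:.4f}, {row['ci_high']:.4f}]"
                )
            lines.append(s)
        return "\n".join(lines)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":  # "case"/"control" style labels
        y = (y == "case").astype(int)
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or 'case'/'control')")
    return y


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(y_true, y_pred) -> MetricsReport:
    """Point estimates of the six confusion-derived metrics."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted labels")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    acc = _ratio(tp + tn, tp + fp + fn + tn)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    return MetricsReport(
        point={
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "accuracy": acc,
            "f1": f1,
        }
    )


def auroc(y_true, scores) -> float:
    """Tie-corrected rank AUROC: P(score_case > score_control) + ½ P(tie)."""
    yt = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(yt.sum())
    n0 = len(yt) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc requires both classes present in y_true")
    r = rankdata(s)
    return float((r[yt == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve via step integration (average precision)."""
    yt = _as_binary(y_true)
    if yt.sum() == 0 or yt.sum() == len(yt):
        raise ValueError("auprc requires both classes present in y_true")
    return float(average_precision_score(yt, np.asarray(scores, dtype=float)))


def _all_metrics(yt: np.ndarray, s: np.ndarray, threshold: float) -> dict[str, float]:
    rep = confusion_metrics(yt, (s >= threshold).astype(int))
    out = dict(rep.point)
    out["auroc"] = auroc(yt, s)
    out["auprc"] = auprc(yt, s)
    return out


def bootstrap_metrics(
    y_true,
    scores,
    spec: BootstrapSpec = BootstrapSpec(),
    threshold: float = 0.5,
) -> MetricsReport:
    """Bootstrap mean, SD and percentile CI for every metric.

    The resampling unit is the (label, score) pair; thresholded metrics are
    recomputed per resample at the fixed ``threshold`` (ties count positive).
    Resamples missing a class are redrawn (bounded retries). Metrics that come
    out undefined in a resample are excluded from that metric's aggregation,
    with the exclusion count reported in ``n_undefined``.
    """
    yt = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n = len(yt)
    if n < 2 or yt.sum() in (0, n):
        raise ValueError("bootstrap requires n >= 2 and both classes observed")
    rng = np.random.default_rng(spec.seed)
    report = MetricsReport(point=_all_metrics(yt, s, threshold), n_resamples=spec.n_resamples)
    draws: dict[str, list[float]] = {m: [] for m in ALL_METRICS}
    for _ in range(spec.n_resamples):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            ys = yt[idx]
            if 0 < ys.sum() < n:
                break
        else:  # pragma: no cover - requires pathological class imbalance
            raise RuntimeError("could not draw a two-class bootstrap resample")
        for m, v in _all_metrics(ys, s[idx], threshold).items():
            draws[m].append(v)
    alpha = 1 - spec.ci_level
    for m, vals in draws.items():
        arr = np.asarray(vals)
        ok = arr[~np.isnan(arr)]
        report.n_undefined[m] = int(np.isnan(arr).sum())
        if len(ok) == 0:
            report.mean[m] = report.sd[m] = float("nan")
            report.ci_low[m] = report.ci_high[m] = float("nan")
            continue
        report.mean[m] = float(ok.mean())
        report.sd[m] = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
        report.ci_low[m] = float(np.percentile(ok, 100 * alpha / 2))
        report.ci_high[m] = float(np.percentile(ok, 100 * (1 - alpha / 2)))
    return report


# --- cohort characteristic tables --------------------------------------------


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (table rendering convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError(f"count {count} exceeds group total {total}")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(
    counts: dict[str, dict[str, int]],
    totals: dict[str, int],
    suppress_at: int | None = 10,
) -> pd.DataFrame:
    """Render per-group category counts as an "n (%)" characteristics table.

    ``counts`` maps group -> {category: count}; ``totals`` gives each group's
    denominator. Percentages are half-up rounded to one decimal. Cells with
    count <= ``suppress_at`` are rendered as "≤ {suppress_at} (≤ {p}%)" for
    privacy (pass ``suppress_at=None`` to disable).
    """
    for g, cats in counts.items():
        if g not in totals:
            raise ValueError(f"no total given for group {g!r}")
        for cat, c in cats.items():
            if c > totals[g]:
                raise ValueError(f"count {c} for {g}/{cat} exceeds group total {totals[g]}")
    categories: list[str] = []
    for cats in counts.values():
        for cat in cats:
            if cat not in categories:
                categories.append(cat)
    table: dict[str, list[str]] = {}
    for g, cats in counts.items():
        col = []
        for cat in categories:
            c = cats.get(cat)
            if c is None:
                col.append("")
            elif suppress_at is not None and c <= suppress_at:
                col.append(f"≤ {suppress_at} (≤ {percent(suppress_at, totals[g])}%)")
            else:
                col.append(f"{c:,} ({percent(c, totals[g])}%)")
        table[f"{g} (N = {totals[g]:,})"] = col
    return pd.DataFrame(table, index=categories)
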
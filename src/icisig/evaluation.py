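"""Classifier metrics, response-rate summaries, and the study's statistics.

Sensitivity/specificity are reported as percentages to one decimal
(rounding half away from zero), matching how clinical performance figures
are customarily printed.  Group comparisons use the two-tailed
Mann-Whitney U test, paired pre/on-treatment comparisons the two-tailed
Wilcoxon signed-rank test (zero differences dropped), and survival uses
Kaplan-Meier product-limit estimates with the two-group log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "response_fractions",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "km_median",
    "logrank_test",
    "round_percent",
]


def round_percent(x: float, decimals: int = 1) -> float:
    """Round half away from zero, to one decimal by default."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with sensitivity/specificity in percent."""

    tp: int
    fn: int
    tn: int
    fp: int
    positive_label: str

    @property
    def sensitivity(self) -> float | None:
        """100*tp/(tp+fn), or None when there are no positives."""
        if self.tp + self.fn == 0:
            return None
        return round_percent(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity(self) -> float | None:
        if self.tn + self.fp == 0:
            return None
        return round_percent(100.0 * self.tn / (self.tn + self.fp))


def confusion_metrics(
    truth: Sequence, predicted: Sequence, positive_label
) -> ConfusionCounts:
    """Confusion counts of ``predicted`` against ``truth``.

    Any label other than ``positive_label`` counts as negative.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    t = np.asarray([x == positive_label for x in truth])
    p = np.asarray([x == positive_label for x in predicted])
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        positive_label=str(positive_label),
    )


def response_fractions(category_counts: dict) -> dict:
    """Percent of tumors in each response category, plus overall responders.

    Durable (DR) and short-lived (SR) responses together count as
    "responding".
    """
    total = sum(category_counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("counts must be non-negative")
    out = {
        f"{k}_percent": round_percent(100.0 * v / total)
        for k, v in category_counts.items()
    }
    responding = category_counts.get("DR", 0) + category_counts.get("SR", 0)
    out["responding_percent"] = round_percent(100.0 * responding / total)
    out["total"] = total
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U for x, p).

    Exact null enumeration for small tie-free samples (n_x + n_y <= 12),
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(pre: Sequence[float], on: Sequence[float]) -> float:
    """Two-tailed Wilcoxon signed-rank p for paired samples (by position).

    Zero differences are dropped; if every difference is zero the test is
    degenerate and p = 1 is returned with a warning.  Exact sign-flip
    enumeration is used for n <= 12 non-zero tie-free differences.
    """
    pre = np.asarray(pre, dtype=float)
    on = np.asarray(on, dtype=float)
    if pre.shape != on.shape:
        raise ValueError("pre and on must have equal length")
    d = on - pre
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    tie_free = len(np.unique(np.abs(d))) == d.size
    method = "exact" if (d.size <= 12 and tie_free) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def _records_frame(records: Sequence[dict] | pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if (df["time"] < 0).any() or not np.isfinite(df["time"]).all():
        raise ValueError("survival times must be finite and non-negative")
    return df


def km_median(records: Sequence[dict] | pd.DataFrame) -> float | None:
    """Kaplan-Meier median survival: smallest t with S(t) <= 0.5.

    ``records`` holds dicts (or a DataFrame) with ``time`` (days) and
    ``event`` (1 = endpoint reached, 0 = censored).  Returns None when the
    survival curve never reaches 0.5.
    """
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_.iloc[:, 0]
    # smallest t with S(t) <= 0.5 (inclusive at exactly 0.5)
    crossed = surv[surv <= 0.5 + 1e-12]
    return None if crossed.empty else float(crossed.index[0])


def logrank_test(
    group_a: Sequence[dict] | pd.DataFrame, group_b: Sequence[dict] | pd.DataFrame
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    a = _records_frame(group_a)
    b = _records_frame(group_b)
    if a["event"].sum() == 0 or b["event"].sum() == 0:
        raise ValueError("each group needs at least one observed event")
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)
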
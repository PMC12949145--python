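"""Per-animal metrics and oestrous-stage statistical comparisons.

The animal is the statistical unit: every recording yields one value per
metric (mean inter-event interval, event rate, propagation speed, component
durations, burst presence, direction counts), and stages are compared with
one-way ANOVA plus Tukey-HSD-adjusted pairwise tests, with residual
normality checked by Shapiro-Wilk.  Results are reported as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import STAGES

#: The six stage pairs in conventional reporting order.
PAIR_ORDER = (
    ("pro-oestrus", "oestrus"),
    ("pro-oestrus", "metoestrus"),
    ("pro-oestrus", "dioestrus"),
    ("oestrus", "metoestrus"),
    ("oestrus", "dioestrus"),
    ("metoestrus", "dioestrus"),
)

METRICS = (
    "interval_s",
    "rate_cpm",
    "rate_hz",
    "speed_mm_s",
    "slow_duration_s",
    "burst_duration_s",
    "burst_presence_pct",
)


def cpm_to_hz(rate_cpm: float) -> float:
    """Events per minute -> events per second."""
    return rate_cpm / 60.0


def event_metrics(events, measurements, fields, recording=None) -> dict:
    """Summarise one analysed recording into per-animal metric values.

    The inter-event interval is the mean of successive differences of the
    event reference times (median activation per event); the rate is its
    reciprocal.  Duration metrics average over channel-event measurements,
    and burst presence is the percentage of analysed windows flagged
    burst-present.  With fewer than two events the interval (and rate) are
    undefined and reported as NaN.
    """
    refs = np.sort([ev.t_ref_s for ev in events])
    if refs.size >= 2:
        interval = float(np.mean(np.diff(refs)))
        rate_cpm = 60.0 / interval
    else:
        interval = rate_cpm = float("nan")

    speeds = [f.mean_speed_mm_s for f in (fields or {}).values() if f is not None]
    ms = list((measurements or {}).values())
    slow = [m.slow_duration_s for m in ms if m.slow_duration_s is not None]
    burst = [m.burst_duration_s for m in ms if m.burst_present and m.burst_duration_s is not None]
    n_windows = len(ms)

    counts = {}
    for f in (fields or {}).values():
        if f is not None:
            counts[f.direction] = counts.get(f.direction, 0) + 1

    return {
        "interval_s": interval,
        "rate_cpm": rate_cpm,
        "rate_hz": cpm_to_hz(rate_cpm),
        "speed_mm_s": float(np.mean(speeds)) if speeds else float("nan"),
        "slow_duration_s": float(np.mean(slow)) if slow else float("nan"),
        "burst_duration_s": float(np.mean(burst)) if burst else float("nan"),
        "burst_presence_pct": (
            100.0 * sum(m.burst_present for m in ms) / n_windows if n_windows else float("nan")
        ),
        "direction_counts": counts,
    }


def metric_rows(animal_id: str, stage: str, metrics: dict) -> pd.DataFrame:
    """One (animal, stage, metric, value) row per scalar metric."""
    rows = [
        {"animal_id": animal_id, "stage": stage, "metric": name, "value": metrics[name]}
        for name in METRICS
        if name in metrics
    ]
    return pd.DataFrame(rows, columns=["animal_id", "stage", "metric", "value"])


def aggregate_by_stage(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean, sample SD (n-1) and n for every metric."""
    clean = table.dropna(subset=["value"])
    out = (
        clean.groupby(["metric", "stage"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


@dataclass
class StageComparison:
    """ANOVA + pairwise comparison of one metric across stages."""

    metric: str
    anova_f: float
    anova_p: float
    shapiro_w: float
    shapiro_p: float
    pairwise: pd.DataFrame  # columns: stage_a, stage_b, p_adj
    diagnostic: str = ""

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_adj"] < 0.05]
        return list(zip(sig["stage_a"], sig["stage_b"]))


def _pairwise_frame(pvals: dict[tuple[str, str], float]) -> pd.DataFrame:
    rows = [
        {"stage_a": a, "stage_b": b, "p_adj": pvals.get((a, b), pvals.get((b, a), np.nan))}
        for a, b in PAIR_ORDER
    ]
    return pd.DataFrame(rows, columns=["stage_a", "stage_b", "p_adj"])


def compare_stages(table: pd.DataFrame, metric: str, adjust: str = "tukey") -> StageComparison:
    """Compare one metric across oestrous stages.

    Shapiro-Wilk runs on the pooled within-stage residuals, the omnibus
    test is a one-way ANOVA, and the six stage pairs are compared with the
    chosen adjustment (``tukey`` by default, ``bonferroni`` or ``none``).
    Degenerate input (zero variance everywhere) yields a diagnostic report
    with NaN statistics rather than an exception.
    """
    sub = table[(table["metric"] == metric)].dropna(subset=["value"])
    groups = {s: g["value"].to_numpy() for s, g in sub.groupby("stage")}
    groups = {s: v for s, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError(f"metric {metric!r} needs >= 2 stages with >= 2 animals")

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[s] * v.size for s, v in groups.items()])
    residuals = np.concatenate([v - v.mean() for v in groups.values()])

    if np.ptp(values) == 0:
        nan6 = _pairwise_frame({p: 1.0 for p in PAIR_ORDER})
        return StageComparison(
            metric, np.nan, np.nan, np.nan, np.nan, nan6, diagnostic="zero variance"
        )

    if np.ptp(residuals) > 0:
        sw_w, sw_p = sstats.shapiro(residuals)
    else:
        sw_w, sw_p = np.nan, np.nan
    anova_f, anova_p = sstats.f_oneway(*groups.values())

    pvals: dict[tuple[str, str], float] = {}
    if adjust == "tukey":
        res = pairwise_tukeyhsd(values, labels)
        uniq = list(res.groupsunique)
        k = 0
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pvals[(uniq[i], uniq[j])] = float(res.pvalues[k])
                k += 1
    elif adjust in ("bonferroni", "none"):
        names = list(groups)
        n_tests = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                _, p = sstats.ttest_ind(groups[names[i]], groups[names[j]])
                if adjust == "bonferroni":
                    p = min(1.0, p * n_tests)
                pvals[(names[i], names[j])] = float(p)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return StageComparison(
        metric=metric,
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        shapiro_w=float(sw_w),
        shapiro_p=float(sw_p),
        pairwise=_pairwise_frame(pvals),
    )


def build_report(table: pd.DataFrame, metrics=METRICS, adjust: str = "tukey") -> pd.DataFrame:
    """P-value table: one row per metric, one column per stage pair."""
    rows = []
    for metric in metrics:
        if metric not in set(table["metric"]):
            continue
        try:
            cmp = compare_stages(table, metric, adjust)
        except ValueError:
            continue
        row = {"metric": metric, "anova_p": cmp.anova_p, "shapiro_p": cmp.shapiro_p}
        for (_, r) in cmp.pairwise.iterrows():
            row[f"{r.stage_a}–{r.stage_b}"] = r.p_adj
        rows.append(row)
    return pd.DataFrame(rows)
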
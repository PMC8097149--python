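"""Group comparison and correlation statistics for VRS metrics.

The statistical layer mirrors the study convention: mean +/- SD group
summaries, pairwise two-sided Mann-Whitney U tests with a Bonferroni
corrected significance threshold (0.05 / 3 comparisons ~ 0.017), and
Pearson correlations of the VRS metrics with seizure duration and with
the course after seizure onset within each seizure group.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "StatReport",
    "mann_whitney_u",
    "pearson_r",
    "bonferroni_threshold",
    "build_report",
]

#: metrics summarised in a cohort report, in table order
REPORT_METRICS = (
    ("vrs_count", "VRS count"),
    ("vrs_volume_mm3", "VRS volume (mm3)"),
    ("wm_volume_mm3", "WM volume (mm3)"),
    ("brain_volume_mm3", "Brain volume (mm3)"),
)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The U statistic uses midranks for ties. The p-value is exact (full
    enumeration of rank assignments) when ``min(n, m) <= 8`` and there are
    no ties; otherwise the normal approximation with continuity and tie
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one variable pair."""

    pair: tuple[str, str]
    r: float
    p: float
    n: int


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Product-moment correlation with a t-transform p (n - 2 df).

    Raises ``ValueError`` for unequal lengths, n < 3 or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        pair=tuple(pair), r=float(res.statistic), p=float(res.pvalue), n=int(x.size)
    )


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Corrected per-comparison threshold ``alpha / m``.

    Returns ``(exact, rounded)`` where ``rounded`` is the exact value
    rounded to three decimals, the form usually printed in reports
    (0.05 / 3 -> 0.017).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    exact = alpha / m
    return exact, round(exact, 3)


@dataclass(frozen=True)
class GroupComparison:
    """One metric's group summary and pairwise tests."""

    metric: str
    group_stats: dict[str, tuple[float, float]]  # group -> (mean, sd)
    pairwise_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]


@dataclass
class StatReport:
    """Cohort-level statistical report."""

    comparisons: list[GroupComparison]
    correlations: list[CorrelationResult]
    alpha: float
    n_comparisons: int
    threshold_exact: float
    threshold_rounded: float
    groups: tuple[str, ...]

    def comparison_table(self) -> pd.DataFrame:
        """Wide table: one row per metric, mean +/- SD per group, p per pair."""
        rows = []
        for comp in self.comparisons:
            row: dict = {"metric": comp.metric}
            for gname, (mean, sd) in comp.group_stats.items():
                row[f"{gname}_mean"] = mean
                row[f"{gname}_sd"] = sd
            for (a, b), p in comp.pairwise_p.items():
                row[f"p_{a}_vs_{b}"] = p
                row[f"sig_{a}_vs_{b}"] = comp.significant[(a, b)]
            rows.append(row)
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": c.pair[0].split(":", 1)[0], "x": c.pair[0].split(":", 1)[1],
                 "y": c.pair[1], "r": c.r, "p": c.p, "n": c.n}
                for c in self.correlations
            ]
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "threshold_exact": self.threshold_exact,
            "threshold_rounded": self.threshold_rounded,
            "groups": list(self.groups),
            "comparisons": [
                {
                    "metric": c.metric,
                    "group_stats": {g: list(v) for g, v in c.group_stats.items()},
                    "pairwise": [
                        {"a": a, "b": b, "p": p, "significant": c.significant[(a, b)]}
                        for (a, b), p in c.pairwise_p.items()
                    ],
                }
                for c in self.comparisons
            ],
            "correlations": [
                {"pair": list(c.pair), "r": c.r, "p": c.p, "n": c.n}
                for c in self.correlations
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_report(
    df: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int = 3,
    metrics: Sequence[tuple[str, str]] = REPORT_METRICS,
) -> StatReport:
    """Build the full statistical report from a per-subject table.

    ``df`` needs columns ``subject_id``, ``group``, the metric columns
    (``vrs_count``, ``vrs_volume_mm3``, ``wm_volume_mm3``,
    ``brain_volume_mm3``) and the covariates ``seizure_duration_min`` /
    ``course_days`` (NaN/absent for controls; control rows therefore carry
    no correlation entries). Groups with missing covariates that are not
    all-missing raise an error naming the offending subjects.
    """
    groups = tuple(dict.fromkeys(df["group"]))
    if len(groups) < 2 or any((df["group"] == g).sum() < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 subjects each")
    thr_exact, thr_rounded = bonferroni_threshold(alpha, n_comparisons)

    comparisons = []
    available = [m for m in metrics if m[0] in df.columns]
    for col, _label in available:
        stats = {}
        for g in groups:
            vals = df.loc[df["group"] == g, col].to_numpy(dtype=float)
            stats[g] = (float(vals.mean()), float(vals.std(ddof=1)))
        pairwise: dict[tuple[str, str], float] = {}
        significant: dict[tuple[str, str], bool] = {}
        for a, b in itertools.combinations(groups, 2):
            xa = df.loc[df["group"] == a, col].to_numpy(dtype=float)
            xb = df.loc[df["group"] == b, col].to_numpy(dtype=float)
            _, p = mann_whitney_u(xa, xb)
            pairwise[(a, b)] = p
            significant[(a, b)] = p < thr_exact
        comparisons.append(
            GroupComparison(
                metric=col, group_stats=stats, pairwise_p=pairwise, significant=significant
            )
        )

    correlations: list[CorrelationResult] = []
    for g in groups:
        sub = df[df["group"] == g]
        for cov in ("seizure_duration_min", "course_days"):
            if cov not in sub.columns:
                continue
            covvals = sub[cov]
            if covvals.isna().all():
                continue  # control group: no seizure covariates
            if covvals.isna().any():
                missing = sub.loc[covvals.isna(), "subject_id"].tolist()
                raise ValueError(
                    f"group {g!r}: missing {cov} for subjects {missing}"
                )
            if len(sub) < 3:
                continue  # Pearson r is undefined below 3 pairs
            for col in ("vrs_count", "vrs_volume_mm3"):
                if col not in sub.columns:
                    continue
                correlations.append(
                    pearson_r(
                        covvals.to_numpy(dtype=float),
                        sub[col].to_numpy(dtype=float),
                        pair=(f"{g}:{cov}", col),
                    )
                )

    return StatReport(
        comparisons=comparisons,
        correlations=correlations,
        alpha=alpha,
        n_comparisons=n_comparisons,
        threshold_exact=thr_exact,
        threshold_rounded=thr_rounded,
        groups=groups,
    )
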
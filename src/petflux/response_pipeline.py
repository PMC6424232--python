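"""Index-lesion selection, percentage-change response classification, and
cohort summary statistics.

Classes are ``PD`` (progression, change strictly above the threshold),
``PR`` (partial response, change strictly below minus the threshold) and
``SD`` (stable) — ``non-PD`` pools SD and PR.  Per-patient change is the
arithmetic mean of the per-lesion percentage changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from petflux.errors import DomainError

__all__ = [
    "METRICS",
    "ResponseResult",
    "CohortSummary",
    "equivalent_sphere_diameter",
    "select_index_lesions",
    "percent_change",
    "classify",
    "patient_change",
    "lesion_percent_changes",
    "patient_percent_changes",
    "classify_patients",
    "cohort_stats",
    "confusion_counts",
]

logger = logging.getLogger(__name__)

#: response metrics, in the order they are reported
METRICS = ("ki", "suv_max", "suv_mean")

DEFAULT_THRESHOLD_PCT = 25.0


def equivalent_sphere_diameter(volume_cm3: float) -> float:
    """Diameter (cm) of the sphere with the given volume (cm^3)."""
    if volume_cm3 < 0:
        raise DomainError("volume must be >= 0")
    return (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def select_index_lesions(
    lesions: pd.DataFrame,
    max_lesions: int = 5,
    min_suv_max: float = 10.0,
    min_diameter_cm: float = 1.0,
) -> pd.DataFrame:
    """Select up to ``max_lesions`` index lesions from a baseline lesion table.

    Keeps lesions with ``suv_max >= min_suv_max`` and equivalent-sphere
    diameter at least ``min_diameter_cm``; ranks by ``suv_max`` descending,
    breaking ties by larger volume and then lexically by ``lesion_id``.
    Returns an empty frame (with a logged warning) when nothing qualifies.
    """
    required = {"lesion_id", "suv_max", "volume_cm3"}
    missing = required - set(lesions.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    diam = lesions["volume_cm3"].map(equivalent_sphere_diameter)
    eligible = lesions[(lesions["suv_max"] >= min_suv_max) & (diam >= min_diameter_cm)]
    if eligible.empty:
        logger.warning("no eligible index lesions found")
        return eligible
    ranked = eligible.sort_values(
        by=["suv_max", "volume_cm3", "lesion_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return ranked.head(max_lesions)


def percent_change(pre_value: float, post_value: float) -> float:
    """``100 * (post - pre) / pre``; requires a positive baseline value."""
    if pre_value <= 0:
        raise DomainError(f"baseline value must be > 0, got {pre_value}")
    # formulated as a ratio so that exact quarter changes (e.g. 0.08 -> 0.06)
    # land exactly on the classification boundary in floating point
    return 100.0 * post_value / pre_value - 100.0


def classify(change: float, threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> str:
    """Map a percentage change to ``PD`` / ``SD`` / ``PR``.

    PD requires a change strictly greater than ``+threshold_pct``; PR a
    change strictly below ``-threshold_pct``; everything else is SD.
    """
    if not math.isfinite(change):
        raise DomainError(f"change must be finite, got {change}")
    if change > threshold_pct:
        return "PD"
    if change < -threshold_pct:
        return "PR"
    return "SD"


def patient_change(lesion_changes: Sequence[float]) -> float:
    """Arithmetic mean of per-lesion percentage changes."""
    values = np.asarray(list(lesion_changes), dtype=float)
    if values.size == 0:
        raise DomainError("lesion change list must be non-empty")
    return float(np.mean(values))


def lesion_percent_changes(lesion_table: pd.DataFrame) -> pd.DataFrame:
    """Per-lesion percentage changes from a tidy baseline/week8 lesion table.

    Expects columns ``patient_id, visit, lesion_id`` plus the metric columns
    ``ki, suv_max, suv_mean`` with visits ``baseline`` and ``week8``; only
    lesions present at both visits are kept.
    """
    for col in ("patient_id", "visit", "lesion_id"):
        if col not in lesion_table.columns:
            raise ValueError(f"lesion table missing column {col!r}")
    wide = lesion_table.pivot_table(
        index=["patient_id", "lesion_id"],
        columns="visit",
        values=list(METRICS),
        aggfunc="first",
    )
    out = {}
    for metric in METRICS:
        pre = wide[(metric, "baseline")]
        post = wide[(metric, "week8")]
        out[f"{metric}_pct_change"] = 100.0 * post / pre - 100.0
    changes = pd.DataFrame(out).dropna().reset_index()
    return changes


def patient_percent_changes(lesion_changes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean of the per-lesion percentage changes."""
    cols = [f"{m}_pct_change" for m in METRICS]
    return lesion_changes.groupby("patient_id", as_index=False)[cols].mean()


def classify_patients(
    patient_changes: pd.DataFrame,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Attach per-metric PD/SD/PR classes and a non-PD flag per patient."""
    out = patient_changes.copy()
    for metric in METRICS:
        out[f"{metric}_class"] = out[f"{metric}_pct_change"].map(
            lambda c: classify(c, threshold_pct)
        )
        out[f"{metric}_non_pd"] = out[f"{metric}_class"] != "PD"
    return out


@dataclass
class ResponseResult:
    """Full classification output: per-lesion and per-patient tables."""

    lesion_changes: pd.DataFrame | None
    patient_classes: pd.DataFrame
    threshold_pct: float = DEFAULT_THRESHOLD_PCT


def _safe_stat(fn, *args) -> tuple[float, float]:
    try:
        res = fn(*args)
        return float(res.statistic), float(res.pvalue)
    except Exception as exc:  # degenerate variance, too few points, ...
        logger.warning("statistic undefined: %s", exc)
        return float("nan"), float("nan")


def _paired_t_with_log_gate(pre: np.ndarray, post: np.ndarray) -> dict:
    """Paired t-test of post vs pre, log-transforming first when a
    Shapiro-Wilk check on the differences rejects normality at alpha=0.05 and
    all values are positive."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    log_transformed = False
    diffs = post - pre
    if pre.size >= 3 and np.ptp(diffs) > 0:
        _, p_norm = stats.shapiro(diffs)
        if p_norm < 0.05 and np.all(pre > 0) and np.all(post > 0):
            log_transformed = True
    if log_transformed:
        stat, p = _safe_stat(stats.ttest_rel, np.log(post), np.log(pre))
    else:
        stat, p = _safe_stat(stats.ttest_rel, post, pre)
    return {"statistic": stat, "pvalue": p, "log_transformed": log_transformed}


@dataclass
class CohortSummary:
    """Cohort-level statistics of a classified response table."""

    group_stats: dict  # metric -> {PD: {mean, sd, n}, non-PD: {...}}
    correlations: dict  # comparison -> {baseline, week8, pct_change: {r, p}}
    paired_tests: dict  # metric -> paired t of week8 vs baseline
    group_comparison: dict  # metric -> two-sample t of PD vs non-PD changes

    def to_dict(self) -> dict:
        return {
            "group_stats": self.group_stats,
            "correlations": self.correlations,
            "paired_tests": self.paired_tests,
            "group_comparison": self.group_comparison,
        }


def cohort_stats(
    patient_changes: pd.DataFrame,
    reference: Mapping[str, str],
    values_table: pd.DataFrame | None = None,
) -> CohortSummary:
    """Cohort statistics: group means/SDs, correlations, and t-tests.

    Parameters
    ----------
    patient_changes : DataFrame
        Per-patient percentage changes (columns ``patient_id`` and
        ``<metric>_pct_change``).
    reference : mapping
        ``patient_id -> "PD" | "non-PD"`` reference-standard labels.
    values_table : DataFrame, optional
        Per-patient (or per-lesion) metric values with columns
        ``patient_id, visit, ki, suv_max, suv_mean`` enabling baseline/week8
        correlations and paired tests.
    """
    df = patient_changes.copy()
    df["reference"] = df["patient_id"].map(dict(reference))
    if df["reference"].isna().any():
        raise ValueError("missing reference label for some patients")

    group_stats: dict = {}
    group_comparison: dict = {}
    for metric in METRICS:
        col = f"{metric}_pct_change"
        per_group = {}
        for label in ("PD", "non-PD"):
            vals = df.loc[df["reference"] == label, col].to_numpy(dtype=float)
            per_group[label] = {
                "mean": float(np.mean(vals)) if vals.size else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
            }
        group_stats[metric] = per_group
        pd_vals = df.loc[df["reference"] == "PD", col].to_numpy(dtype=float)
        npd_vals = df.loc[df["reference"] == "non-PD", col].to_numpy(dtype=float)
        if pd_vals.size >= 2 and npd_vals.size >= 2:
            stat, p = _safe_stat(stats.ttest_ind, pd_vals, npd_vals)
        else:
            stat, p = float("nan"), float("nan")
        group_comparison[metric] = {"statistic": stat, "pvalue": p}

    correlations: dict = {}
    for other in ("suv_max", "suv_mean"):
        entry: dict = {}
        r, p = _safe_stat(
            stats.pearsonr,
            df["ki_pct_change"].to_numpy(dtype=float),
            df[f"{other}_pct_change"].to_numpy(dtype=float),
        )
        entry["pct_change"] = {"r": r, "pvalue": p}
        if values_table is not None:
            for visit in ("baseline", "week8"):
                sub = values_table[values_table["visit"] == visit]
                r, p = _safe_stat(
                    stats.pearsonr,
                    sub["ki"].to_numpy(dtype=float),
                    sub[other].to_numpy(dtype=float),
                )
                entry[visit] = {"r": r, "pvalue": p}
        correlations[f"ki_vs_{other}"] = entry

    paired_tests: dict = {}
    if values_table is not None:
        index_cols = [
            c for c in ("patient_id", "lesion_id") if c in values_table.columns
        ]
        wide = values_table.pivot_table(
            index=index_cols, columns="visit", values=list(METRICS), aggfunc="first"
        ).dropna()
        for metric in METRICS:
            paired_tests[metric] = _paired_t_with_log_gate(
                wide[(metric, "baseline")].to_numpy(),
                wide[(metric, "week8")].to_numpy(),
            )

    return CohortSummary(
        group_stats=group_stats,
        correlations=correlations,
        paired_tests=paired_tests,
        group_comparison=group_comparison,
    )


def confusion_counts(
    patient_classes: pd.DataFrame, reference: Mapping[str, str]
) -> dict:
    """Per-metric counts of correctly identified PD / non-PD and false positives."""
    df = patient_classes.copy()
    df["reference"] = df["patient_id"].map(dict(reference))
    if df["reference"].isna().any():
        raise ValueError("missing reference label for some patients")
    out: dict = {}
    for metric in METRICS:
        cls = df[f"{metric}_class"]
        is_pd_call = cls == "PD"
        ref_pd = df["reference"] == "PD"
        ref_npd = df["reference"] == "non-PD"
        out[metric] = {
            "pd_identified": int((ref_pd & is_pd_call).sum()),
            "pd_total": int(ref_pd.sum()),
            "non_pd_identified": int((ref_npd & ~is_pd_call).sum()),
            "non_pd_total": int(ref_npd.sum()),
            "false_positives": int((ref_npd & is_pd_call).sum()),
        }
    return out
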
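"""Cohort-level statistics: descriptives, group tests, correlations, ROC/AUC.

The cohort table is long-format pandas: one row per
(subject_id, group, tract, metric) with the central-segment value. Group
labels follow the four-grade design control / subCI / MCI / dementia; the
ROC contrast pools MCI ∪ dementia as the clinically-significant-CI case class
against controls (subCI is excluded from that contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "descriptives",
    "kruskal_wallis",
    "dunn_posthoc",
    "chi_square",
    "anova_oneway",
    "metric_correlations",
    "roc_auc",
    "auc_table",
    "CASE_GROUPS",
]

#: Groups pooled as the "clinically significant cognitive impairment" class.
CASE_GROUPS = ("MCI", "dementia")

#: Metrics expected to decrease with disease grade (ROC orientation bookkeeping).
DECREASING_METRICS = frozenset({"FA", "MK", "AK", "RK", "AWF", "INTRA", "NDI"})


@dataclass
class ROCResult:
    metric: str
    tract: str
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    orientation: str           # "higher_in_cases" | "lower_in_cases"
    youden_threshold: float
    sensitivity: float
    specificity: float


# ---------------------------------------------------------------------------
# descriptives and group tests

def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Per group × tract × metric median and quartiles, Me[Q25; Q75] format.

    Quantiles use the linear-interpolation definition. Raises on an empty
    group slice (guaranteed non-empty by construction of the groupby)."""
    def _agg(s: pd.Series) -> pd.Series:
        q25, med, q75 = np.quantile(s, [0.25, 0.5, 0.75])
        return pd.Series({
            "median": med, "q25": q25, "q75": q75,
            "formatted": f"{med:.2f} [{q25:.2f}; {q75:.2f}]",
            "n": len(s),
        })

    if table.empty:
        raise ValueError("empty cohort table")
    out = (
        table.groupby(["group", "tract", "metric"], observed=True)["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    return out


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1).

    All-identical data returns (0, 1)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(*groups: np.ndarray, correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    Returns a symmetric k×k adjusted-p matrix (unit diagonal). Bonferroni
    multiplies by the number of pairs and caps at 1."""
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term: sum over tie groups of (t³ − t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[starts[i] : starts[i + 1]].mean() for i in range(k)]
    )
    n_pairs = k * (k - 1) // 2
    P = np.eye(k)
    np.fill_diagonal(P, 1.0)
    for i, j in combinations(range(k), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        if correction == "bonferroni":
            p = min(1.0, p * n_pairs)
        elif correction not in (None, "none"):
            raise ValueError(f"unknown correction {correction!r}")
        P[i, j] = P[j, i] = p
    return pd.DataFrame(P)


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson χ² of independence without continuity correction."""
    table = np.asarray(table)
    if np.any(table < 0) or table.ndim != 2:
        raise ValueError("contingency table must be a nonnegative 2D array")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway(*groups: np.ndarray) -> tuple[float, float]:
    """Classic one-way ANOVA F test.

    Zero within-group variance with equal means makes F undefined → NaN."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [np.mean(g) for g in groups]
    within = sum(np.sum((np.asarray(g) - m) ** 2) for g, m in zip(groups, means))
    if within == 0 and np.allclose(means, means[0]):
        return np.nan, np.nan
    if within == 0:
        return np.inf, 0.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def metric_correlations(table: pd.DataFrame, tract: str) -> pd.DataFrame:
    """Spearman correlation matrix across metrics for one tract.

    Pairwise-complete over subjects; constant metrics yield NaN entries."""
    sub = table[table["tract"] == tract]
    wide = sub.pivot_table(index="subject_id", columns="metric", values="value")
    if len(wide.dropna(how="any")) < 3:
        raise ValueError("need >= 3 subjects with complete metric vectors")
    return wide.corr(method="spearman")


# ---------------------------------------------------------------------------
# ROC / AUC

def _auc_mannwhitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC by concordant-pair counting with half credit for ties."""
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    m, n = len(cases), len(controls)
    # V10[i]: fraction of controls each case beats; V01[j]: fraction of cases beating control j
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: str = "",
    tract: str = "",
    case_label: object = 1,
) -> ROCResult:
    """ROC analysis of one score against a binary case/control label.

    AUC via the Mann–Whitney concordant-pair formula (ties half credit); the
    score orientation is auto-selected so AUC ≥ 0.5 and recorded. The CI and
    the p-value against AUC = 0.5 use DeLong's variance (normal theory). The
    Youden threshold maximizes sensitivity + specificity − 1, ties broken
    toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == case_label
    cases = scores[is_case]
    controls = scores[~is_case]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")

    auc_raw = _auc_mannwhitney(cases, controls)
    if auc_raw >= 0.5:
        orientation = "higher_in_cases"
        s_cases, s_controls = cases, controls
    else:
        orientation = "lower_in_cases"
        s_cases, s_controls = -cases, -controls
    auc = _auc_mannwhitney(s_cases, s_controls)

    var = _delong_variance(s_cases, s_controls)
    se = np.sqrt(var)
    z975 = sps.norm.ppf(0.975)
    ci_low = max(0.0, auc - z975 * se)
    ci_high = min(1.0, auc + z975 * se)
    if se > 0:
        p_half = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p_half = 0.0 if auc != 0.5 else 1.0

    # Youden threshold on the oriented scores (case-like = above threshold)
    pooled = np.unique(np.concatenate([s_cases, s_controls]))
    best_j, best_thr, best_sens, best_spec = -np.inf, pooled[0], 0.0, 0.0
    for thr in pooled:
        sens = float(np.mean(s_cases >= thr))
        spec = float(np.mean(s_controls < thr))
        j = sens + spec - 1.0
        if j > best_j:  # strict: ties keep the lower threshold
            best_j, best_thr, best_sens, best_spec = j, thr, sens, spec
    if orientation == "lower_in_cases":
        best_thr = -best_thr
    return ROCResult(
        metric, tract, auc, float(ci_low), float(ci_high), float(p_half),
        orientation, float(best_thr), best_sens, best_spec,
    )


def auc_table(
    cohort: pd.DataFrame,
    metrics: list[str] | None = None,
    tracts: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ROC of every metric × tract for clinically significant CI vs control.

    Cases = MCI ∪ dementia; subCI rows are dropped from the contrast.
    Cells significant at ``alpha`` are formatted "AUC (lo–hi), p"; the rest
    report the p-value only (sparse-table convention)."""
    sub = cohort[cohort["group"].isin(("control",) + CASE_GROUPS)].copy()
    sub["case"] = sub["group"].isin(CASE_GROUPS).astype(int)
    metrics = metrics or sorted(sub["metric"].unique())
    tracts = tracts or sorted(sub["tract"].unique())
    rows = []
    for metric in metrics:
        for tract in tracts:
            cell = sub[(sub["metric"] == metric) & (sub["tract"] == tract)]
            if cell.empty:
                continue
            res = roc_auc(
                cell["value"].to_numpy(), cell["case"].to_numpy(),
                metric=metric, tract=tract,
            )
            if res.p_vs_half < alpha:
                formatted = (
                    f"{res.auc:.3f} ({res.ci_low:.3f}–{res.ci_high:.3f}), "
                    f"p={res.p_vs_half:.3g}"
                )
            else:
                formatted = f"p={res.p_vs_half:.3g}"
            rows.append({
                "metric": metric, "tract": tract, "auc": res.auc,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p_vs_half, "orientation": res.orientation,
                "youden_threshold": res.youden_threshold,
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "formatted": formatted,
            })
    return pd.DataFrame(rows)
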
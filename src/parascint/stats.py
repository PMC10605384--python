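"""Cohort statistics: severity grouping, descriptives, Spearman correlations,
normality-gated two-group tests, ROC / Youden cut-off analysis, and ICC(2,1).

The analysis mirrors a standard clinical workflow: hypercalcemia severity is
dichotomized on serum calcium (mild [10.5, 11.5) vs marked >= 11.5 mg/dL);
continuous variables are summarized as mean +/- SD when Shapiro-Wilk accepts
normality and median (min-max) otherwise; two-group comparisons use the
independent t test (Levene-gated pooling) when both groups pass normality and
the Mann-Whitney U test otherwise; discriminative ability is assessed by the
empirical ROC curve with trapezoidal AUC, a DeLong confidence interval, and
the Youden-index-optimal cut-off J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "severity_group",
    "descriptive_summary",
    "spearman",
    "compare_groups",
    "GroupComparison",
    "RocResult",
    "roc_curve",
    "youden_index",
    "youden_optimal_cutoff",
    "icc",
    "run_study_analysis",
]

#: calcium bounds (mg/dL) of the mild-hypercalcemia stratum
MILD_LOWER = 10.5
MILD_UPPER = 11.5

ALPHA = 0.05


def severity_group(calcium: float) -> str:
    """Severity stratum from serum calcium (mg/dL).

    mild: 10.5 <= Ca < 11.5; marked: Ca >= 11.5. Values below 10.5 fall
    outside the hypercalcemic cohort definition and raise.
    """
    if not np.isfinite(calcium):
        raise ValueError("calcium must be finite")
    if calcium < MILD_LOWER:
        raise ValueError(
            f"calcium {calcium:.2f} mg/dL is below the {MILD_LOWER} mg/dL "
            "eligibility bound (ineligible record)"
        )
    return "mild" if calcium < MILD_UPPER else "marked"


def _is_normal(values: np.ndarray, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality gate (constant samples count as non-normal)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False
    return sps.shapiro(values).pvalue >= alpha


def descriptive_summary(
    values, normal: bool | None = None, decimals: int = 2
) -> dict:
    """Mean +/- SD for normal data, median (min-max) otherwise.

    Returns the numbers plus a formatted string in the house style; the
    normality gate is Shapiro-Wilk at alpha=0.05 unless ``normal`` is forced.
    """
    values = np.asarray(pd.Series(values).dropna(), dtype=float)
    if values.size < 2:
        raise ValueError("descriptive summary needs at least 2 non-missing values")
    if normal is None:
        normal = _is_normal(values)
    if normal:
        mean, sd = values.mean(), values.std(ddof=1)
        return {
            "kind": "mean_sd",
            "mean": float(mean),
            "sd": float(sd),
            "n": int(values.size),
            "text": f"{mean:.{decimals}f} ± {sd:.{decimals}f}",
        }
    med, lo, hi = np.median(values), values.min(), values.max()
    return {
        "kind": "median_range",
        "median": float(med),
        "min": float(lo),
        "max": float(hi),
        "n": int(values.size),
        "text": f"{med:.{decimals}f} ({lo:.{decimals}f}–{hi:.{decimals}f})",
    }


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the rank vectors; the p-value uses the
    t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    n = x.size
    if n < 4:
        raise ValueError("spearman requires n >= 4")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rank correlation undefined: zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_summaries: dict[str, dict]
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float


def compare_groups(values, groups, variable: str = "") -> GroupComparison:
    """Two-group comparison with a normality-gated test choice.

    Shapiro-Wilk (alpha 0.05) on each group chooses between the independent t
    test (equal variances decided by Levene at alpha 0.05) and the two-sided
    Mann-Whitney U test (normal approximation, tie-corrected, with continuity
    correction).
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    levels = sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a = df.loc[df["g"] == levels[0], "v"].to_numpy(dtype=float)
    b = df.loc[df["g"] == levels[1], "v"].to_numpy(dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs at least 3 values")
    normal = _is_normal(a) and _is_normal(b)
    if normal:
        equal_var = sps.levene(a, b).pvalue >= ALPHA
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test_used = "t"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
        )
        test_used = "mann_whitney"
    return GroupComparison(
        variable=variable,
        group_summaries={
            str(lev): descriptive_summary(vals, normal=normal)
            for lev, vals in ((levels[0], a), (levels[1], b))
        },
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci95: tuple[float, float]
    direction: str  # greater_is_positive | lesser_is_positive
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    curve: np.ndarray  # ordered (FPR, TPR) points
    p_value: float
    thresholds: np.ndarray = field(repr=False, default=None)

    @property
    def cutoff_text(self) -> str:
        sign = ">" if self.direction == "greater_is_positive" else "<"
        return f"{sign}{self.cutoff:.2f}"


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via mid-rank structural components."""
    m, n = pos.size, neg.size
    all_v = np.concatenate([pos, neg])
    r_all = sps.rankdata(all_v)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # P(X > Y) component per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(marker, labels, direction: str = "auto") -> RocResult:
    """Empirical ROC over all realized thresholds, with DeLong AUC inference.

    ``labels`` is boolean-like (True = diseased/positive class). For the
    'greater' direction a record is called positive when marker >= cutoff (the
    cutoff is a realized marker value); 'lesser' mirrors this. ``auto`` picks
    the direction giving AUC >= 0.5. The trapezoidal AUC equals the
    tie-corrected Mann-Whitney U / (n1 n2).
    """
    marker = np.asarray(marker, dtype=float)
    y = np.asarray(labels).astype(bool)
    if marker.shape != y.shape or marker.ndim != 1:
        raise ValueError("marker and labels must be paired 1-D arrays")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if direction == "auto":
        auc_g, _ = _delong_variance(marker[y], marker[~y])
        direction = "greater_is_positive" if auc_g >= 0.5 else "lesser_is_positive"
    if direction not in ("greater_is_positive", "lesser_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    score = marker if direction == "greater_is_positive" else -marker
    pos, neg = score[y], score[~y]
    n1, n0 = pos.size, neg.size

    # empirical curve over distinct scores, descending: positive iff score >= t
    thr = np.unique(score)[::-1]
    tpr = (pos[None, :] >= thr[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thr[:, None]).mean(axis=1)
    curve = np.vstack([
        np.concatenate([[0.0], fpr, [1.0]]),
        np.concatenate([[0.0], tpr, [1.0]]),
    ]).T
    auc, var = _delong_variance(pos, neg)
    se = np.sqrt(var)
    z975 = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z975 * se), min(1.0, auc + z975 * se))
    p = 1.0 if se == 0 and auc == 0.5 else float(
        2.0 * sps.norm.sf(abs(auc - 0.5) / se) if se > 0 else 0.0
    )

    # Youden-optimal realized cutoff: max J, ties -> higher sensitivity,
    # then cutoff nearest the marker median; ties resolved at 1e-12 so that
    # float round-off cannot split an exact tie
    j = tpr + (1.0 - fpr) - 1.0
    med = np.median(marker)
    cut_real = thr if direction == "greater_is_positive" else -thr
    order = np.lexsort(
        (np.abs(cut_real - med), -np.round(tpr, 12), -np.round(j, 12))
    )
    k = order[0]
    return RocResult(
        auc=float(auc),
        auc_ci95=(float(ci[0]), float(ci[1])),
        direction=direction,
        cutoff=float(cut_real[k]),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        youden_j=float(j[k]),
        curve=curve,
        p_value=p,
        thresholds=cut_real,
    )


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {v}")
    return float(sensitivity + specificity - 1.0)


def youden_optimal_cutoff(roc: RocResult) -> tuple[float, float, float, float]:
    """(cutoff, sensitivity, specificity, J) at the Youden-optimal threshold."""
    return roc.cutoff, roc.sensitivity, roc.specificity, roc.youden_j


def icc(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix. From the two-way ANOVA
    mean squares (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("ICC needs >= 5 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete (no missing cells)")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ratings matrix (zero variance)")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# report assembly

MARKER_COLUMNS = [
    "pth", "calcium", "phosphorus", "vitd",
    "elbr", "eltr", "dlbr", "dltr", "ri", "svol", "pth_svol",
]

_CORR_ROWS = ["pth", "calcium", "phosphorus", "vitd",
              "elbr", "eltr", "dlbr", "dltr", "ri"]
_CORR_COLS = ["svol", "pth_svol", "elbr", "dlbr", "ri"]


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def run_study_analysis(cohort: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Run the full statistical stage on a cohort table.

    Emits a report bundle with descriptive statistics, the marker x imaging
    Spearman correlation block, the severity-group comparison, the ROC /
    Youden cut-off table for predicting marked hypercalcemia, and — when
    location labels are present — the lower-right vs lower-left comparison.
    """
    cohort = cohort.copy()
    if "severity" not in cohort:
        cohort["severity"] = [severity_group(c) for c in cohort["calcium"]]
    present = [c for c in MARKER_COLUMNS if c in cohort.columns]
    bundle: dict = {"n": int(len(cohort)), "notices": []}

    bundle["descriptives"] = {
        v: descriptive_summary(cohort[v]) for v in present
    }
    bundle["severity_counts"] = cohort["severity"].value_counts().to_dict()

    corr: dict[str, dict] = {}
    for a in _CORR_ROWS:
        if a not in cohort:
            continue
        corr[a] = {}
        for b in _CORR_COLS:
            if b not in cohort or a == b:
                continue
            pair = cohort[[a, b]].dropna()
            rho, p = spearman(pair[a], pair[b])
            corr[a][b] = {"rho": rho, "p": p, "p_text": _format_p(p),
                          "n": int(len(pair))}
    bundle["correlations"] = corr

    severity = cohort["severity"]
    if severity.nunique() == 2 and severity.value_counts().min() >= 3:
        bundle["severity_comparison"] = {
            v: compare_groups(cohort[v], severity, variable=v)
            for v in present if v != "calcium"
        }
        y = (severity == "marked").to_numpy()
        roc_block = {}
        for v in present:
            if v == "calcium":
                continue  # calcium defines the groups
            sub = cohort[v].notna().to_numpy()
            if y[sub].all() or not y[sub].any():
                continue
            roc_block[v] = roc_curve(cohort[v].to_numpy()[sub], y[sub])
        bundle["roc_table"] = roc_block
    else:
        bundle["notices"].append(
            "severity comparison skipped: need two groups with n >= 3"
        )

    if "location" in cohort.columns:
        sub = cohort[cohort["location"].isin(["lower_right", "lower_left"])]
        if sub["location"].nunique() == 2 and sub["location"].value_counts().min() >= 3:
            bundle["location_comparison"] = {
                v: compare_groups(sub[v], sub["location"], variable=v)
                for v in present
            }
        else:
            bundle["notices"].append(
                "location comparison skipped: too few lower-site records"
            )
    return bundle
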
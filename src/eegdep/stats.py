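"""Subject-level AI scores, scale correlations, and group comparisons.

Image-level AI scores are aggregated to one score per subject (mean by
default) and correlated against questionnaire scales with Spearman's
rank correlation. Group contrasts use an independent-samples t-test
when both groups pass Shapiro-Wilk normality (p > 0.05), otherwise the
Mann-Whitney U test; categorical variables use the chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import EPQ_SUBSCALES, SCL90_SUBSCALES

SCALE_COLUMNS = ("sds", "sas") + SCL90_SUBSCALES + EPQ_SUBSCALES


@dataclass
class SubjectAIScore:
    subject_id: str
    ai_score: float
    n_images: int


@dataclass
class GroupTestResult:
    variable: str
    test_name: str  # "t-test" | "mann-whitney" | "chi-squared"
    statistic: float
    p_value: float


def subject_ai_scores(
    image_scores: pd.DataFrame, manifest: pd.DataFrame | None = None,
    agg: str = "mean",
) -> list[SubjectAIScore]:
    """Aggregate image-level scores to one AI score per subject.

    ``image_scores`` needs ``score`` plus either ``subject_id`` or a
    manifest mapping rows to subjects. Every image must map to a
    subject.
    """
    if agg not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {agg!r}")
    df = image_scores.copy()
    if "subject_id" not in df.columns:
        if manifest is None:
            raise ValueError("need subject_id column or a manifest")
        df = df.merge(
            manifest[["path", "subject_id"]], on="path", how="left", validate="m:1"
        )
    if df["subject_id"].isna().any():
        orphans = df[df["subject_id"].isna()]
        raise ValueError(f"{len(orphans)} image scores have no subject mapping")
    out = []
    fn = np.mean if agg == "mean" else np.median
    for sid, grp in df.groupby("subject_id", sort=True):
        out.append(
            SubjectAIScore(
                subject_id=str(sid),
                ai_score=float(fn(grp["score"].to_numpy())),
                n_images=len(grp),
            )
        )
    return out


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p.

    Returns (nan, nan) for a constant input rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    subject_scores: list[SubjectAIScore], roster: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and p of the subject AI score against every scale."""
    scores = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subject_scores],
            "ai_score": [s.ai_score for s in subject_scores],
        }
    )
    merged = scores.merge(roster, on="subject_id", how="inner", validate="1:1")
    rows = []
    for col in SCALE_COLUMNS:
        if col not in merged.columns:
            continue
        if len(merged) < 3:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearman(
                merged["ai_score"].to_numpy(), merged[col].to_numpy()
            )
        rows.append({"scale": col, "rho": rho, "p": p, "n": len(merged)})
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    normality_alpha: float = 0.05,
) -> GroupTestResult:
    """Two-group comparison with a normality-gated test choice."""
    groups = [g for _, g in table.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    a = groups[0][variable]
    b = groups[1][variable]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not pd.api.types.is_numeric_dtype(table[variable]):
        ct = pd.crosstab(table[group_col], table[variable])
        chi2, p, _, _ = sps.chi2_contingency(ct, correction=False)
        return GroupTestResult(variable, "chi-squared", float(chi2), float(p))
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    normal = True
    for v in (av, bv):
        if np.ptp(v) == 0:
            normal = False
            break
        if len(v) >= 3 and sps.shapiro(v).pvalue <= normality_alpha:
            normal = False
            break
    if normal:
        stat, p = sps.ttest_ind(av, bv)
        return GroupTestResult(variable, "t-test", float(stat), float(p))
    stat, p = sps.mannwhitneyu(av, bv, alternative="two-sided")
    return GroupTestResult(variable, "mann-whitney", float(stat), float(p))


def chi_squared(table_2x2: np.ndarray) -> GroupTestResult:
    """Chi-squared test on a contingency table (no Yates correction)."""
    arr = np.asarray(table_2x2, dtype=float)
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return GroupTestResult("table", "chi-squared", float(chi2), float(p))


def group_comparison_table(
    roster: pd.DataFrame,
    group_col: str = "group",
    variables: tuple[str, ...] = SCALE_COLUMNS,
) -> pd.DataFrame:
    rows = []
    for var in variables:
        if var not in roster.columns:
            continue
        res = compare_groups(roster, var, group_col=group_col)
        rows.append(
            {
                "variable": var,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
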
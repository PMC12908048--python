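"""Group comparisons, correlations with FDR control, and simple derived
clinical quantities (PLR, rounded proportions).

Test-selection policy for continuous variables: a Shapiro–Wilk normality
screen at 0.05 in each group chooses Student's t (both normal) vs
Mann–Whitney U, unless the caller forces a test. Categorical 2×k tables use
chi-square without continuity correction unless any expected cell is below
5, in which case Fisher's exact test is used (2×2 only). Every result
records which test actually ran.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BIOMARKERS, CohortMetadata, ValidationError

__all__ = [
    "GroupComparison",
    "CorrelationRecord",
    "percent",
    "plr",
    "compare_groups",
    "correlate",
    "bh_fdr",
    "biomarker_infection_correlations",
    "group_comparison_table",
]


@dataclass
class GroupComparison:
    variable: str
    test: str  # {"t", "mann_whitney", "chi_square", "fisher"}
    statistic: float
    p_value: float
    summaries: dict


@dataclass
class CorrelationRecord:
    x: str
    y: str
    method: str
    r: float
    p: float
    p_adjusted: float | None = None
    n: int = 0


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places.

    Exact decimal arithmetic so printed-table proportions (e.g. 37/80 →
    46.3) are reproduced without binary-float round-half-even artifacts.
    """
    if denominator == 0:
        raise ValidationError("zero denominator")

    def dec(v) -> Decimal:
        f = float(v)
        return Decimal(int(f)) if f.is_integer() else Decimal(str(f))

    q = dec(numerator) / dec(denominator) * 100
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def plr(platelets: float, lymphocytes: float) -> float:
    """Platelet-to-lymphocyte ratio (both in cells/µL)."""
    platelets = np.asarray(platelets, dtype=float)
    lymphocytes = np.asarray(lymphocytes, dtype=float)
    if (lymphocytes <= 0).any():
        raise ValidationError("lymphocytes must be > 0")
    if (platelets <= 0).any():
        raise ValidationError("platelets must be > 0")
    out = platelets / lymphocytes
    return float(out) if out.ndim == 0 else out


def _continuous_summary(x: np.ndarray, normal: bool) -> dict:
    if normal:
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def compare_groups(
    values,
    labels,
    kind: str = "continuous",
    variable: str = "",
    policy: str = "auto",
    equal_var: bool = True,
    yates: bool = False,
) -> GroupComparison:
    """Two-group comparison of one variable.

    ``kind="continuous"``: values are numeric; ``policy`` is ``"auto"``
    (Shapiro screen), ``"t"`` or ``"mann_whitney"``.
    ``kind="categorical"``: values are category codes; a 2×k contingency
    table is formed against the group labels.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(groups)}")
    values = np.asarray(values)

    if kind == "continuous":
        x = values[labels == groups[0]].astype(float)
        y = values[labels == groups[1]].astype(float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 3 or len(y) < 3:
            raise ValidationError("need >= 3 observations per group")
        if policy == "auto":
            normal = all(
                np.ptp(g) > 0 and stats.shapiro(g).pvalue > 0.05 for g in (x, y)
            )
            test = "t" if normal else "mann_whitney"
        elif policy in ("t", "mann_whitney"):
            test = policy
        else:
            raise ValidationError(f"unknown policy {policy!r}")
        if test == "t":
            res = stats.ttest_ind(x, y, equal_var=equal_var)
            summaries = {
                str(groups[0]): _continuous_summary(x, True),
                str(groups[1]): _continuous_summary(y, True),
            }
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            summaries = {
                str(groups[0]): _continuous_summary(x, False),
                str(groups[1]): _continuous_summary(y, False),
            }
        return GroupComparison(variable, test, float(res.statistic), float(res.pvalue), summaries)

    if kind != "categorical":
        raise ValidationError(f"kind must be 'continuous' or 'categorical', got {kind!r}")

    tab = pd.crosstab(pd.Series(labels, name="group"), pd.Series(values, name=variable))
    if (tab.sum(axis=1) == 0).any() or tab.shape[1] < 2:
        raise ValidationError("empty category or single-level categorical variable")
    observed = tab.to_numpy()
    expected = stats.contingency.expected_freq(observed)
    use_fisher = (expected < 5).any() and observed.shape == (2, 2)
    if use_fisher:
        stat, p = stats.fisher_exact(observed)
        test = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(observed, correction=yates)
        test = "chi_square"
    summaries = {
        str(g): {
            str(c): {"n": int(tab.loc[g, c]), "percent": percent(tab.loc[g, c], tab.loc[g].sum())}
            for c in tab.columns
        }
        for g in tab.index
    }
    return GroupComparison(variable, test, float(stat), float(p), summaries)


def correlate(x, y, method: str = "spearman", x_name: str = "x", y_name: str = "y") -> CorrelationRecord:
    """Pairwise-complete correlation; Spearman uses mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return CorrelationRecord(x_name, y_name, method, float(r), float(p), n=len(x))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("expected a non-empty 1-D p-value vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def biomarker_infection_correlations(
    metadata: CohortMetadata, method: str = "spearman"
) -> pd.DataFrame:
    """Correlation of each serum biomarker with the 0/1 infection label,
    BH-adjusted across the biomarker family."""
    y = metadata.infection.to_numpy(dtype=float)
    records = []
    for name in BIOMARKERS:
        if name not in metadata.data.columns:
            continue
        rec = correlate(metadata.biomarker(name), y, method=method, x_name=name, y_name="infection")
        records.append(rec)
    if not records:
        raise ValidationError("no biomarker columns present in metadata")
    padj = bh_fdr([r.p for r in records])
    rows = []
    for rec, q in zip(records, padj):
        rec.p_adjusted = float(q)
        rows.append(
            {"biomarker": rec.x, "method": rec.method, "r": rec.r, "p": rec.p,
             "p_adjusted": rec.p_adjusted, "n": rec.n}
        )
    return pd.DataFrame(rows).set_index("biomarker")


def group_comparison_table(metadata: CohortMetadata) -> pd.DataFrame:
    """Baseline-characteristics comparison of every standard metadata column
    between infected and non-infected samples (Table-1 style)."""
    df = metadata.data
    labels = metadata.infection.to_numpy()
    rows = []
    continuous = ["age", "nihss", "platelets", "lymphocytes", *BIOMARKERS]
    categorical = ["sex", "dysphagia"]
    if "platelets" in df.columns and "lymphocytes" in df.columns:
        df = df.assign(plr=plr(df["platelets"].to_numpy(), df["lymphocytes"].to_numpy()))
        continuous.append("plr")
    for col in continuous:
        if col not in df.columns:
            continue
        cmp = compare_groups(df[col].to_numpy(dtype=float), labels, "continuous", variable=col)
        rows.append({"variable": col, "test": cmp.test, "statistic": cmp.statistic,
                     "p_value": cmp.p_value})
    for col in categorical:
        if col not in df.columns:
            continue
        cmp = compare_groups(df[col].to_numpy(), labels, "categorical", variable=col)
        rows.append({"variable": col, "test": cmp.test, "statistic": cmp.statistic,
                     "p_value": cmp.p_value})
    return pd.DataFrame(rows).set_index("variable")
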
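"""Dysbiosis indices: MDI, SDI, data-driven panel derivation, and the
age–dysbiosis correlation analysis.

MDI (Microbial Dysbiosis Index) uses the printed pseudocount form

    MDI = log10[(1 + sum pathogenic abundance) / (1 + sum beneficial abundance)]

with *unweighted* sums. SDI (Stroke Dysbiosis Index) is the weighted
log-ratio generalisation

    SDI = log10[(eps + sum_i w_i a_i) / (eps + sum_j w_j a_j)]

over the panel's enriched (i) and depleted (j) taxa. With all weights 1 and
eps = 1 the SDI reduces *exactly* to the MDI — that identity anchors the two
definitions. The original SDI reference weights are not reproducible here
(the healthy-reference dataset is unavailable), so panels either ship as
JSON fixtures or are derived from labelled data via :func:`derive_panel`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, CohortMetadata, DysbiosisPanel, ValidationError
from .stats import bh_fdr

__all__ = [
    "mdi",
    "sdi",
    "compute_indices",
    "panel_coverage",
    "derive_panel",
    "age_sdi_correlation",
]

_REL_TOL = 1e-6


def _panel_sums(sample: pd.Series, panel: DysbiosisPanel, weighted: bool) -> tuple[float, float]:
    def total(group: dict[str, float]) -> float:
        s = 0.0
        for taxon, w in group.items():
            a = float(sample.get(taxon, 0.0))
            if a < 0:
                raise ValidationError(f"negative abundance for {taxon!r}")
            s += (w if weighted else 1.0) * a
        return s

    return total(panel.enriched), total(panel.depleted)


def _check_relative(sample: pd.Series) -> None:
    total = float(np.asarray(sample, dtype=float).sum())
    if total > 1.0 + 1e-3:
        raise ValidationError(
            f"sample abundances sum to {total:.4g}; convert count-mode data to "
            "relative abundances first"
        )


def mdi(sample: pd.Series, panel: DysbiosisPanel) -> float:
    """Microbial Dysbiosis Index of one relative-abundance sample.

    Panel taxa absent from the sample contribute 0 (reflected separately in
    :func:`panel_coverage`).
    """
    _check_relative(sample)
    s_path, s_bene = _panel_sums(sample, panel, weighted=False)
    return float(np.log10((1.0 + s_path) / (1.0 + s_bene)))


def sdi(sample: pd.Series, panel: DysbiosisPanel, epsilon: float = 1.0) -> float:
    """Stroke Dysbiosis Index: weighted log-ratio with pseudocount ``epsilon``."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    _check_relative(sample)
    s_enr, s_dep = _panel_sums(sample, panel, weighted=True)
    return float(np.log10((epsilon + s_enr) / (epsilon + s_dep)))


def panel_coverage(table: AbundanceTable, panel: DysbiosisPanel) -> float:
    """Fraction of panel taxa present as columns of the table."""
    present = sum(1 for t in panel.taxa if t in table.data.columns)
    return present / len(panel.taxa)


def compute_indices(
    table: AbundanceTable, panel: DysbiosisPanel, epsilon: float = 1.0
) -> pd.DataFrame:
    """Per-sample SDI/MDI table with the panel coverage recorded per row."""
    if table.mode != "relative":
        raise ValidationError("indices require a relative-mode table; use to_relative()")
    cov = panel_coverage(table, panel)
    out = pd.DataFrame(index=table.data.index)
    out["sdi"] = [sdi(table.data.loc[s], panel, epsilon) for s in table.sample_ids]
    out["mdi"] = [mdi(table.data.loc[s], panel) for s in table.sample_ids]
    out["panel_coverage"] = cov
    return out


def derive_panel(
    table: AbundanceTable, labels, alpha: float = 0.05, level: str = "species"
) -> DysbiosisPanel:
    """Derive an enriched/depleted panel from labelled samples.

    Per-taxon two-sided Mann–Whitney tests with BH-FDR control; taxa with
    adjusted p < ``alpha`` are assigned by the sign of the group median
    difference (group-1 minus group-0), weighted by |median difference|
    normalised so the largest weight is 1.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValidationError("derive_panel requires exactly two groups")
    mask1 = labels == groups[1]
    if mask1.sum() < 3 or (~mask1).sum() < 3:
        raise ValidationError("need at least 3 samples per group")
    vals = table.values
    pvals = np.ones(table.n_taxa)
    med_diff = np.zeros(table.n_taxa)
    for j in range(table.n_taxa):
        a, b = vals[mask1, j], vals[~mask1, j]
        med_diff[j] = np.median(a) - np.median(b)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # constant taxon, untestable
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    padj = bh_fdr(pvals)
    hits = np.flatnonzero(padj < alpha)
    if hits.size == 0:
        raise ValidationError("both panel lists empty: no taxa pass the FDR threshold")
    w_max = np.abs(med_diff[hits]).max()
    if w_max <= 0:
        raise ValidationError("both panel lists empty: significant taxa have zero median shift")
    enriched, depleted = {}, {}
    for j in hits:
        w = abs(med_diff[j]) / w_max
        if w <= 0:
            continue
        name = table.taxon_ids[j]
        (enriched if med_diff[j] > 0 else depleted)[name] = float(w)
    if not enriched or not depleted:
        raise ValidationError("both panel lists empty" if not (enriched or depleted)
                              else "one panel list empty: shifts all share one sign")
    return DysbiosisPanel(enriched=enriched, depleted=depleted, level=level)


def age_sdi_correlation(
    metadata: CohortMetadata,
    index_result: pd.DataFrame,
    stratify: str = "by-group",
) -> pd.DataFrame:
    """Spearman correlation between age and SDI, pooled and/or per group.

    Returns one row per stratum with columns stratum, n, rho, p. With group
    mean shifts in both variables the pooled rho can exceed both within-group
    rhos (a Simpson-style reversal), which is why both views are reported.
    """
    if stratify not in ("pooled", "by-group"):
        raise ValidationError(f"stratify must be 'pooled' or 'by-group', got {stratify!r}")
    df = metadata.data.join(index_result[["sdi"]], how="inner")
    records = []

    def one(name: str, sub: pd.DataFrame) -> None:
        sub = sub.dropna(subset=["age", "sdi"])
        if len(sub) < 4:
            raise ValidationError(f"stratum {name!r} has fewer than 4 samples")
        if sub["age"].nunique() == 1:
            raise ValidationError(f"constant age vector in stratum {name!r}")
        rho, p = stats.spearmanr(sub["age"], sub["sdi"])
        records.append({"stratum": name, "n": len(sub), "rho": float(rho), "p": float(p)})

    one("pooled", df)
    if stratify == "by-group":
        for g, sub in df.groupby(df["infection"].astype(int)):
            one("infected" if g == 1 else "non-infected", sub)
    return pd.DataFrame.from_records(records)
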
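"""Microbial co-occurrence networks from pairwise taxon correlations.

Taxa passing a prevalence filter are correlated pairwise (Spearman by
default), p-values are BH-FDR adjusted across all tested pairs, and an edge
is drawn when |r| >= r_min and adjusted p < fdr_alpha. Isolated nodes are
dropped from the node count by default (flag to retain), reflecting the
convention that reported network sizes count connected taxa only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, ValidationError
from .stats import bh_fdr

__all__ = ["NetworkParams", "CoNetwork", "build_network", "network_summary"]


@dataclass(frozen=True)
class NetworkParams:
    method: str = "spearman"
    prevalence_min: float = 0.2
    r_min: float = 0.6
    fdr_alpha: float = 0.05
    keep_isolated: bool = False

    def validate(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ValidationError(f"method must be 'spearman' or 'pearson', got {self.method!r}")
        if not (0 <= self.prevalence_min <= 1):
            raise ValidationError("prevalence_min must lie in [0, 1]")
        if not (0 <= self.r_min <= 1):
            raise ValidationError("r_min must lie in [0, 1]")
        if not (0 < self.fdr_alpha <= 1):
            raise ValidationError("fdr_alpha must lie in (0, 1]")


@dataclass
class CoNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # taxon_a, taxon_b, r, p, p_adjusted
    params: NetworkParams
    n_samples: int
    tested_pairs: int


def _pairwise_correlations(x: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """(r, p) matrices for all column pairs; constant columns give NaN."""
    n, t = x.shape
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[~np.isfinite(r)] = np.nan
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    # two-sided p from the t approximation (exact enough for n >= 5)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isnan(r)] = np.nan
    # perfectly correlated pairs have p -> 0
    p[np.abs(r) >= 1 - 1e-12] = np.finfo(float).tiny
    return r, p


def build_network(
    table: AbundanceTable,
    sample_mask=None,
    params: NetworkParams | None = None,
    **overrides,
) -> CoNetwork:
    """Build the co-occurrence network for (a subgroup of) a cohort.

    ``sample_mask`` selects the group (boolean array over samples, or None
    for all samples).
    """
    if params is not None and overrides:
        raise ValidationError("pass either params or keyword overrides, not both")
    params = params if params is not None else NetworkParams(**overrides)
    params.validate()

    vals = table.values
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        vals = vals[sample_mask]
    n = vals.shape[0]
    if n < 5:
        raise ValidationError(f"group too small for network analysis (n={n} < 5)")

    prevalence = (vals > 0).mean(axis=0)
    keep = prevalence >= params.prevalence_min
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    sub = vals[:, keep]

    g = nx.Graph()
    if params.keep_isolated:
        g.add_nodes_from(taxa)
    edge_rows: list[dict] = []
    tested = 0
    if len(taxa) >= 2:
        r, p = _pairwise_correlations(sub, params.method)
        iu = np.triu_indices(len(taxa), k=1)
        r_flat, p_flat = r[iu], p[iu]
        ok = ~np.isnan(p_flat)
        tested = int(ok.sum())
        if tested:
            padj = np.full(p_flat.shape, np.nan)
            padj[ok] = bh_fdr(np.clip(p_flat[ok], np.finfo(float).tiny, 1.0))
            hit = ok & (np.abs(r_flat) >= params.r_min) & (padj < params.fdr_alpha)
            for a, b, rv, pv, qv in zip(
                iu[0][hit], iu[1][hit], r_flat[hit], p_flat[hit], padj[hit]
            ):
                ta, tb = taxa[a], taxa[b]
                g.add_edge(ta, tb, r=float(rv), p_adjusted=float(qv))
                edge_rows.append(
                    {"taxon_a": ta, "taxon_b": tb, "r": float(rv),
                     "p": float(pv), "p_adjusted": float(qv)}
                )
    edges = pd.DataFrame(edge_rows, columns=["taxon_a", "taxon_b", "r", "p", "p_adjusted"])
    return CoNetwork(g, edges, params, n, tested)


def network_summary(net: CoNetwork) -> dict:
    """Node/edge counts, mean degree, density and connected components."""
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    return {
        "nodes": n_nodes,
        "edges": n_edges,
        "mean_degree": (2 * n_edges / n_nodes) if n_nodes else 0.0,
        "density": nx.density(g) if n_nodes > 1 else 0.0,
        "components": nx.number_connected_components(g) if n_nodes else 0,
    }
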
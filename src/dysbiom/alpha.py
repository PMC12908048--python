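"""Per-sample alpha-diversity indices.

Shannon entropy (natural log by default), Pielou evenness J = H / ln S,
Gini–Simpson 1 - sum(p^2), and the Chao1 richness estimator
(bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` by default,
where F1/F2 are singleton/doubleton counts). Chao1 needs raw counts;
calling it on relative abundances is an error, not a silent rescale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, ValidationError

__all__ = ["shannon", "pielou", "simpson", "chao1", "alpha_table"]

_SUM_TOL = 1e-6


def _as_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("expected a 1-D proportion vector")
    if (p < 0).any():
        raise ValidationError("negative entries in proportion vector")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"proportions must sum to 1 (got {p.sum():.6g})")
    return p


def shannon(p, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i (zeros contribute 0).

    ``base=None`` gives nats; pass ``base=2`` for bits.
    """
    p = _as_proportions(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def pielou(p) -> float:
    """Evenness J = H / ln S over the S taxa with positive abundance."""
    p = _as_proportions(p)
    s = int((p > 0).sum())
    if s < 2:
        raise ValidationError("Pielou evenness undefined for a single-taxon sample")
    return shannon(p) / float(np.log(s))


def simpson(p) -> float:
    """Gini–Simpson index 1 - sum p_i^2."""
    p = _as_proportions(p)
    return float(1.0 - (p**2).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 estimated richness from integer counts.

    The bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is finite
    even with no doubletons; the classic form ``S_obs + F1^2 / (2 F2)`` is
    available by flag and falls back to the bias-corrected estimate when
    F2 = 0.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError("expected a 1-D count vector")
    if (c < 0).any():
        raise ValidationError("negative counts")
    if not np.allclose(c, np.round(c), atol=1e-9):
        raise ValidationError("non-integer count vector; Chao1 requires raw counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1**2 / (2.0 * f2)


def alpha_table(table: AbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample index table: shannon, pielou, simpson (+ chao1 in count mode).

    Samples with a single observed taxon get NaN Pielou evenness rather than
    aborting the whole table.
    """
    rows = {}
    for sid in table.sample_ids:
        vec = table.data.loc[sid].to_numpy(dtype=float)
        if table.mode == "count":
            total = vec.sum()
            if total <= 0:
                raise ValidationError(f"all-zero sample {sid!r}")
            p = vec / total
        else:
            p = vec
        rec = {
            "shannon": shannon(p, base=base),
            "simpson": simpson(p),
        }
        try:
            rec["pielou"] = pielou(p)
        except ValidationError:
            rec["pielou"] = np.nan
        if table.mode == "count":
            rec["chao1"] = chao1(vec)
        rows[sid] = rec
    cols = ["shannon", "pielou", "simpson"] + (["chao1"] if table.mode == "count" else [])
    return pd.DataFrame.from_dict(rows, orient="index")[cols]
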
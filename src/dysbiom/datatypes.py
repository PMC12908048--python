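"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects with samples in rows and taxa in
columns; the thin dataclass wrappers here exist to carry the *mode* of a
table (relative vs count), to centralise validation, and to give the rest of
the package one vocabulary for samples, taxa and panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "CohortMetadata",
    "DysbiosisPanel",
    "DistanceMatrix",
    "BIOMARKERS",
]


class ValidationError(ValueError):
    """An input violated a structural invariant; message names the field."""


#: Canonical serum biomarker column names, in Table-2 order.
BIOMARKERS = ("nmdar", "butyrate", "tmao", "rankl", "ifabp", "lps")

_REL_ROWSUM_TOL = 1e-6
_REL_RENORM_TOL = 1e-3


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon ids as columns.
    mode:
        ``"relative"`` (rows sum to 1) or ``"count"`` (non-negative integers).
    """

    data: pd.DataFrame
    mode: str = "relative"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.mode not in ("relative", "count"):
            raise ValidationError(f"mode must be 'relative' or 'count', got {self.mode!r}")
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("empty abundance table")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric cells in abundance table")
        vals = vals.astype(float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite values in abundance table")
        if (vals < 0).any():
            raise ValidationError("negative values in abundance table")
        if self.mode == "relative":
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_ROWSUM_TOL
            if bad.any():
                raise ValidationError(
                    "row sum out of tolerance for samples "
                    f"{list(df.index[bad])} (sums {sums[bad].round(6).tolist()})"
                )
        else:
            if not np.allclose(vals, np.round(vals), atol=1e-9):
                raise ValidationError("non-integer count in count-mode table")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, mode: str = "relative", renormalize: bool = True
    ) -> "AbundanceTable":
        """Build a table, renormalising relative rows whose sum is within
        ``1e-3`` of 1 (rounding slack in exported tables); larger deviations
        are a hard error."""
        df = df.copy()
        if mode == "relative" and renormalize:
            vals = df.to_numpy(dtype=float)
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_RENORM_TOL
            if bad.any():
                raise ValidationError(
                    "row sum out of tolerance for samples "
                    f"{list(df.index[bad])} (sums {sums[bad].round(6).tolist()})"
                )
            df = pd.DataFrame(
                vals / sums[:, None], index=df.index, columns=df.columns
            )
        return cls(df, mode)

    def to_relative(self) -> "AbundanceTable":
        """Row-normalise (counts → relative abundances)."""
        if self.mode == "relative":
            return self
        vals = self.values
        sums = vals.sum(axis=1)
        if (sums <= 0).any():
            raise ValidationError("all-zero row cannot be normalised")
        return AbundanceTable(
            pd.DataFrame(vals / sums[:, None], index=self.data.index, columns=self.data.columns),
            "relative",
        )


@dataclass
class CohortMetadata:
    """Per-sample clinical record: infection label, demographics, blood counts
    and the serum biomarker panel. Extra columns are preserved untouched."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def infection(self) -> pd.Series:
        return self.data["infection"].astype(int)

    def biomarker(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise ValidationError(f"biomarker column {name!r} missing from metadata")
        return self.data[name].astype(float)

    def validate(self) -> None:
        df = self.data
        if df.shape[0] == 0:
            raise ValidationError("empty metadata table")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        if "infection" not in df.columns:
            raise ValidationError("metadata missing required 'infection' column")
        inf = df["infection"]
        if inf.isna().any():
            raise ValidationError("missing infection label for some samples")
        vals = set(pd.unique(inf))
        if not vals <= {0, 1, True, False}:
            raise ValidationError(f"infection must be binary 0/1, got values {sorted(map(str, vals))}")
        for col in ("platelets", "lymphocytes"):
            if col in df.columns:
                present = df[col].dropna()
                if (present <= 0).any():
                    raise ValidationError(f"{col} must be > 0 when present")


@dataclass
class DysbiosisPanel:
    """Weighted lists of infection/stroke-associated ("enriched") and
    control-associated ("depleted") taxa feeding the SDI/MDI log-ratios."""

    enriched: dict[str, float]
    depleted: dict[str, float]
    level: str = "species"

    def __post_init__(self) -> None:
        self.enriched = {k: float(v) for k, v in self.enriched.items()}
        self.depleted = {k: float(v) for k, v in self.depleted.items()}
        self.validate()

    def validate(self) -> None:
        if not self.enriched or not self.depleted:
            raise ValidationError("both panel lists must be non-empty")
        overlap = set(self.enriched) & set(self.depleted)
        if overlap:
            raise ValidationError(f"overlapping panel: {sorted(overlap)}")
        for name, w in {**self.enriched, **self.depleted}.items():
            if not np.isfinite(w) or w <= 0:
                raise ValidationError(f"panel weight for {name!r} must be > 0, got {w}")
        if self.level not in ("genus", "species"):
            raise ValidationError(f"panel level must be 'genus' or 'species', got {self.level!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.enriched) + list(self.depleted)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample ids."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "braycurtis"
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        d = self.values
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} does not match {n} sample ids")
        if not np.isfinite(d).all():
            raise ValidationError("non-finite distances")
        if (d < 0).any():
            raise ValidationError("negative distances")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("non-zero diagonal in distance matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
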
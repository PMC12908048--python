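"""Readers/writers for the pipeline's tabular artifacts.

Formats (all plain text, UTF-8, '.' decimal):

* abundance table — TSV, header row of taxon ids, first column ``sample_id``
* metadata — CSV, one row per sample, required column ``infection``
* dysbiosis panel — JSON ``{"level": ..., "enriched": {...}, "depleted": {...}}``
  (lists are accepted for the taxa maps; weights then default to 1)
* distance matrix — square TSV with sample-id header row and column
* run config — YAML
"""

from __future__ import annotations

import datetime
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import AbundanceTable, CohortMetadata, DistanceMatrix, DysbiosisPanel, ValidationError

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_panel",
    "write_panel",
    "read_distance",
    "write_distance",
    "read_config",
    "log_event",
]


def read_abundance(path: str | Path, mode: str = "relative") -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty abundance table in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cells in {path}: {exc}") from exc
    if mode == "count":
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals), atol=1e-9):
            raise ValidationError(f"non-integer count in {path}")
        df = df.round().astype(int)
        return AbundanceTable(df, "count")
    return AbundanceTable.from_dataframe(df, "relative")


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    df = table.data
    if table.mode == "count":
        df = df.round().astype(int)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, index_col=0)
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, index_label="sample_id")


def read_panel(path: str | Path) -> DysbiosisPanel:
    with open(path) as fh:
        raw = json.load(fh)
    if "enriched" not in raw or "depleted" not in raw:
        raise ValidationError("panel JSON must contain 'enriched' and 'depleted'")

    def as_map(entry) -> dict[str, float]:
        if isinstance(entry, dict):
            return {str(k): float(v) for k, v in entry.items()}
        # bare list of taxa -> unit weights
        return {str(t): 1.0 for t in entry}

    return DysbiosisPanel(
        enriched=as_map(raw["enriched"]),
        depleted=as_map(raw["depleted"]),
        level=raw.get("level", "species"),
    )


def write_panel(panel: DysbiosisPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"level": panel.level, "enriched": panel.enriched, "depleted": panel.depleted},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_distance(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row/column ids disagree")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"run config {path} must be a YAML mapping")
    return cfg


def log_event(stage: str, stream=None, **fields) -> str:
    """Emit one timestamped ``key=value`` log line; returns the line."""
    stream = stream if stream is not None else sys.stderr
    stamp = datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    parts = [f"ts={stamp}", f"stage={stage}"] + [f"{k}={v}" for k, v in fields.items()]
    line = " ".join(parts)
    print(line, file=stream)
    return line
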